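"""Synthetic cohort generator for parallel PHQ-9 / GAD-7 trajectory analyses.

Emulates a messaging-therapy cohort assessed at weeks 0, 3, 6, 9 and 12:
latent trajectory classes with quadratic mean growth on both symptom scales,
integer totals clipped to scale range, monotone discrete-time dropout, and
heavy-tailed word-count engagement covariates that (optionally) shift class
membership through a multinomial logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .scales import PHQ9, GAD7

__all__ = [
    "VISIT_WEEKS",
    "CovariateSpec",
    "SimSpec",
    "PanelDataset",
    "generate_cohort",
    "default_study_spec",
]

VISIT_WEEKS: tuple[int, ...] = (0, 3, 6, 9, 12)
N_VISITS = len(VISIT_WEEKS)
OUTCOMES = ("phq9", "gad7")
SCALES = {"phq9": PHQ9, "gad7": GAD7}

AGE_BANDS = ("18-25", "26-35", "36-49", "50+")
EDUCATION_LEVELS = ("Bachelor Degree or Higher", "High School Diploma")
GENDERS = ("Female", "Male")
EXPERIENCE_BANDS = ("<5 Years", "5-9 Years", "10+ Years")


@dataclass
class CovariateSpec:
    """Distributions for subject and therapist covariates.

    Word rates are log-normal to mimic the heavy right tail of words/week
    engagement metrics (cohort mean ~788, SD ~4791 for patients); the
    log-normal (mu, sigma) pairs below are moment-matched approximations.
    """

    age_band_probs: tuple = (0.24, 0.55, 0.179, 0.031)
    female_prob: float = 0.789
    bachelor_prob: float = 0.749
    experience_probs: tuple = (0.35, 0.35, 0.30)
    orientation_probs: dict = field(default_factory=lambda: {
        "cbt": 0.60, "third_wave": 0.25, "dynamic": 0.20})
    patient_words_lognorm: tuple = (4.85, 1.91)
    therapist_words_lognorm: tuple = (4.69, 1.87)

    def validate(self) -> None:
        for name, probs in (("age_band_probs", self.age_band_probs),
                            ("experience_probs", self.experience_probs)):
            if abs(sum(probs) - 1.0) > 1e-8:
                raise ValueError(f"{name} must sum to 1")
        for p in (self.female_prob, self.bachelor_prob,
                  *self.orientation_probs.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimSpec:
    """Full description of a simulated cohort.

    ``class_params`` has shape (K, 2, 3): per class, per outcome
    (PHQ-9 then GAD-7), the (intercept, slope, quadratic) triple on the
    coded-time scale t = 0..4 (visit index).  ``residual_sd`` has shape
    (2, 5): per outcome, per visit.  ``membership_logits`` has shape
    (K, 3): class-specific coefficients on (bachelor+, standardized log
    patient words/week, standardized log therapist words/week); class
    intercepts are calibrated internally so marginal class frequencies
    match ``class_weights`` even when logits are non-zero.
    """

    n_subjects: int
    class_weights: np.ndarray
    class_params: np.ndarray
    residual_sd: np.ndarray
    dropout_hazard: np.ndarray  # scalar broadcast or per-class, in [0, 1)
    membership_logits: np.ndarray
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    covariate_missing_rate: float = 0.0
    missing_covariates: tuple = ("age_band", "education",
                                 "patient_words_per_week",
                                 "therapist_words_per_week")
    class_names: Optional[tuple] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        self.class_params = np.asarray(self.class_params, dtype=float)
        self.residual_sd = np.broadcast_to(
            np.asarray(self.residual_sd, dtype=float), (2, N_VISITS)).copy()
        self.dropout_hazard = np.broadcast_to(
            np.asarray(self.dropout_hazard, dtype=float),
            (self.n_classes,)).copy()
        self.membership_logits = np.asarray(self.membership_logits,
                                            dtype=float)

    @property
    def n_classes(self) -> int:
        return len(self.class_weights)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if np.any(self.class_weights <= 0) or \
                abs(self.class_weights.sum() - 1.0) > 1e-8:
            raise ValueError("class_weights must be positive and sum to 1")
        K = self.n_classes
        if self.class_params.shape != (K, 2, 3):
            raise ValueError(
                f"class_params must have shape ({K}, 2, 3), "
                f"got {self.class_params.shape}")
        if np.any(self.residual_sd <= 0):
            raise ValueError("residual_sd must be positive")
        if np.any(self.dropout_hazard < 0) or np.any(self.dropout_hazard >= 1):
            raise ValueError("dropout_hazard must lie in [0, 1)")
        if self.membership_logits.shape != (K, 3):
            raise ValueError(f"membership_logits must have shape ({K}, 3)")
        if not 0.0 <= self.covariate_missing_rate <= 0.4:
            # the imputation step downstream only accepts ~40% missingness
            raise ValueError("covariate_missing_rate must lie in [0, 0.4]")
        self.covariate_spec.validate()
        if self.class_names is not None and len(self.class_names) != K:
            raise ValueError("class_names length must equal number of classes")

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        for key in ("class_weights", "class_params", "residual_sd",
                    "dropout_hazard", "membership_logits"):
            raw[key] = np.asarray(raw[key]).tolist()
        raw["missing_covariates"] = list(self.missing_covariates)
        if self.class_names is not None:
            raw["class_names"] = list(self.class_names)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cov = raw.pop("covariate_spec", None)
        spec = cls(covariate_spec=CovariateSpec(**cov) if cov else
                   CovariateSpec(), **{
                       k: (np.asarray(v) if k in (
                           "class_weights", "class_params", "residual_sd",
                           "dropout_hazard", "membership_logits") else
                           tuple(v) if k in ("missing_covariates",
                                             "class_names") else v)
                       for k, v in raw.items()})
        return spec


@dataclass
class PanelDataset:
    """Long-format visit data plus subject covariates.

    ``visits`` holds one row per *observed* visit with columns
    ``subject_id``, ``week``, ``phq9``, ``gad7``.  ``covariates`` holds one
    row per subject.  ``class_truth`` is present only for simulated cohorts.
    """

    visits: pd.DataFrame
    covariates: pd.DataFrame
    class_truth: Optional[np.ndarray] = None
    weeks: tuple = VISIT_WEEKS
    meta: dict = field(default_factory=dict)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.covariates["subject_id"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (subject_ids, Y, mask) with Y, mask shaped (n, 2, 5).

        Unobserved cells of Y are 0 with mask False.
        """
        ids = self.subject_ids
        idx = {s: i for i, s in enumerate(ids)}
        widx = {w: j for j, w in enumerate(self.weeks)}
        n = len(ids)
        Y = np.zeros((n, 2, N_VISITS))
        M = np.zeros((n, 2, N_VISITS), dtype=bool)
        rows = self.visits["subject_id"].map(idx).to_numpy()
        cols = self.visits["week"].map(widx).to_numpy()
        for o, name in enumerate(OUTCOMES):
            vals = self.visits[name].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            Y[rows[ok], o, cols[ok]] = vals[ok]
            M[rows[ok], o, cols[ok]] = True
        return ids, Y, M

    def validate(self) -> None:
        ids, Y, M = self.to_arrays()
        observed_any = M.any(axis=1)  # (n, visits)
        if not observed_any[:, 0].all():
            raise ValueError("baseline visit must be observed for everyone")
        # monotone dropout: once a visit is fully unobserved, later ones are too
        seen = observed_any.astype(int)
        if not self.meta.get("intermittent_missingness", False):
            if np.any(np.diff(seen, axis=1) > 0):
                raise ValueError("dropout pattern is not monotone")
        for o, name in enumerate(OUTCOMES):
            vals = Y[:, o, :][M[:, o, :]]
            sc = SCALES[name]
            if vals.size and (vals.min() < sc.total_min or
                              vals.max() > sc.total_max):
                raise ValueError(f"{name} totals outside scale range")

    def write_csv(self, visits_path, covariates_path,
                  meta_path=None) -> None:
        self.visits.to_csv(visits_path, index=False)
        self.covariates.to_csv(covariates_path, index=False)
        if meta_path is not None:
            meta = dict(self.meta)
            with open(meta_path, "w") as fh:
                yaml.safe_dump(meta, fh, sort_keys=False)


def _membership_design(cov: pd.DataFrame) -> np.ndarray:
    """Covariates entering the class-membership logit, on a fixed scale.

    Columns: bachelor+ indicator, log1p patient and therapist words/week,
    each word column centered/scaled by fixed constants (5, 2) so the
    default logit coefficients are roughly per-SD effects.
    """
    educ = (cov["education"] == EDUCATION_LEVELS[0]).to_numpy(float)
    pw = (np.log1p(cov["patient_words_per_week"].to_numpy(float)) - 5.0) / 2.0
    tw = (np.log1p(cov["therapist_words_per_week"].to_numpy(float)) - 5.0) / 2.0
    return np.column_stack([educ, pw, tw])


def _calibrated_intercepts(X: np.ndarray, gamma: np.ndarray,
                           target: np.ndarray, n_iter: int = 60) -> np.ndarray:
    """Class intercepts making marginal membership match ``target`` weights."""
    a = np.log(target)
    base = X @ gamma.T
    for _ in range(n_iter):
        logits = a + base
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        a += np.log(target / P.mean(axis=0))
        a -= a[0]
    return a


def _draw_covariates(spec: SimSpec, rng: np.random.Generator) -> pd.DataFrame:
    cs = spec.covariate_spec
    n = spec.n_subjects
    mu_p, sd_p = cs.patient_words_lognorm
    mu_t, sd_t = cs.therapist_words_lognorm
    cov = pd.DataFrame({
        "subject_id": np.arange(n),
        "age_band": rng.choice(AGE_BANDS, size=n, p=cs.age_band_probs),
        "gender": np.where(rng.random(n) < cs.female_prob, *GENDERS),
        "education": np.where(rng.random(n) < cs.bachelor_prob,
                              *EDUCATION_LEVELS),
        "patient_words_per_week": np.round(
            rng.lognormal(mu_p, sd_p, size=n), 1),
        "therapist_words_per_week": np.round(
            rng.lognormal(mu_t, sd_t, size=n), 1),
        "therapist_experience": rng.choice(EXPERIENCE_BANDS, size=n,
                                           p=cs.experience_probs),
    })
    for name, p in cs.orientation_probs.items():
        cov[f"orientation_{name}"] = (rng.random(n) < p).astype(int)
    return cov


def generate_cohort(spec: SimSpec,
                    rng: Optional[np.random.Generator] = None) -> PanelDataset:
    """Simulate a cohort according to ``spec``.

    Covariates are drawn first; class membership follows a multinomial logit
    on (education, log word rates) with intercepts calibrated to the target
    class weights; symptom totals are class mean trajectory plus independent
    Gaussian visit noise, rounded and clipped to scale range; monotone
    dropout then removes whole visits; finally covariates are masked MCAR at
    ``covariate_missing_rate``.  Fully reproducible given ``spec.seed``.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    n, K = spec.n_subjects, spec.n_classes
    cov = _draw_covariates(spec, rng)

    # class membership
    if np.any(spec.membership_logits != 0.0):
        X = _membership_design(cov)
        a = _calibrated_intercepts(X, spec.membership_logits,
                                   spec.class_weights)
        logits = a + X @ spec.membership_logits.T
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
    else:
        P = np.broadcast_to(spec.class_weights, (n, K))
    u = rng.random(n)
    classes = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
    classes = np.minimum(classes, K - 1)

    # outcomes: mean trajectory + noise, rounded and clipped to scale range
    t = np.arange(N_VISITS, dtype=float)
    design = np.column_stack([np.ones_like(t), t, t ** 2])  # (5, 3)
    mu = spec.class_params @ design.T                        # (K, 2, 5)
    noise = rng.standard_normal((n, 2, N_VISITS)) * spec.residual_sd
    Y = mu[classes] + noise
    for o, name in enumerate(OUTCOMES):
        sc = SCALES[name]
        Y[:, o, :] = np.clip(np.rint(Y[:, o, :]), sc.total_min, sc.total_max)

    # monotone dropout: discrete-time hazard per inter-visit interval
    hazard = spec.dropout_hazard[classes]                    # (n,)
    drops = rng.random((n, N_VISITS - 1)) < hazard[:, None]
    # last observed visit index: first interval with a dropout event
    any_drop = drops.any(axis=1)
    last_visit = np.where(any_drop, drops.argmax(axis=1), N_VISITS - 1)
    observed = np.arange(N_VISITS) <= last_visit[:, None]    # (n, 5)

    rows = []
    sid = np.repeat(np.arange(n), N_VISITS)
    wk = np.tile(np.array(VISIT_WEEKS), n)
    obs_flat = observed.ravel()
    visits = pd.DataFrame({
        "subject_id": sid[obs_flat],
        "week": wk[obs_flat],
        "phq9": Y[:, 0, :].ravel()[obs_flat],
        "gad7": Y[:, 1, :].ravel()[obs_flat],
    })
    del rows

    # weeks in treatment derived from the dropout time
    completer = last_visit == N_VISITS - 1
    weeks_in_treatment = np.where(
        completer, 12.0,
        np.round(3.0 * last_visit + rng.random(n) * 3.0, 1))
    cov["weeks_in_treatment"] = weeks_in_treatment

    # MCAR covariate masking
    if spec.covariate_missing_rate > 0:
        for col in spec.missing_covariates:
            mask = rng.random(n) < spec.covariate_missing_rate
            cov.loc[mask, col] = np.nan

    meta = {
        "seed": int(spec.seed),
        "n_subjects": int(n),
        "n_classes": int(K),
        "completer_fraction": float(completer.mean()),
        "class_names": (list(spec.class_names)
                        if spec.class_names is not None else None),
    }
    panel = PanelDataset(visits=visits, covariates=cov,
                         class_truth=classes, meta=meta)
    panel.validate()
    return panel


DEFAULT_CLASS_NAMES = ("recovery", "acute_recovery", "chronic",
                       "elevated_chronic", "depression_improvement",
                       "anxiety_improvement")

# Per class, per outcome (PHQ-9, GAD-7): (intercept, slope, quadratic) on
# coded time t = 0..4.  Shapes follow the qualitative class descriptions:
# recovery = moderate anxiety / mild depression falling to subclinical;
# acute recovery = high both, sharp early drop; chronic = high, marginal
# improvement; elevated chronic = higher, flat; single-condition improvement
# classes = moderate, improving into milder severity.  These are
# configuration defaults, not estimates from any dataset.
_DEFAULT_CLASS_PARAMS = np.array([
    # recovery (mild-moderate -> subclinical, steady decline)
    [[10.0, -2.7, 0.34], [12.0, -2.8, 0.33]],
    # acute recovery (high -> subclinical, steep early drop)
    [[18.0, -6.0, 0.85], [17.0, -5.5, 0.75]],
    # chronic (high, marginal improvement)
    [[16.0, -0.7, 0.05], [15.0, -0.6, 0.05]],
    # elevated chronic (higher, flat; kept clear of the scale ceilings)
    [[21.0, -0.2, 0.0], [17.0, -0.1, 0.0]],
    # depression improvement (PHQ improves into mild, GAD stays moderate)
    [[14.0, -2.4, 0.28], [12.0, -0.5, 0.03]],
    # anxiety improvement (GAD improves into mild, PHQ stays near-moderate)
    [[12.0, -0.5, 0.03], [15.0, -2.4, 0.27]],
])

# Class-membership shifts relative to the recovery class, acting on
# (bachelor+, std log patient words, std log therapist words): higher
# education and patient engagement favor the recovery classes, more
# therapist words the non-remitting classes.
_DEFAULT_MEMBERSHIP_LOGITS = np.array([
    [0.0, 0.0, 0.0],
    [0.0, 0.1, 0.1],
    [-0.5, -0.35, 0.5],
    [-1.0, -0.4, 0.8],
    [-0.55, -0.4, 0.55],
    [-0.55, -0.3, 0.6],
])

# hazard h with (1 - h)^4 = 0.5624 completers over the four intervals
_DEFAULT_HAZARD = 1.0 - 0.5624 ** 0.25


def default_study_spec(n_subjects: int = 10_000, seed: int = 0,
                       covariate_missing_rate: float = 0.15) -> SimSpec:
    """Six-class cohort template with the published class proportions.

    Weights are (23.7, 7.0, 22.6, 9.8, 20.0, 16.9)% for recovery, acute
    recovery, chronic, elevated chronic, depression improvement and anxiety
    improvement; dropout leaves ~56% completers.  Trajectory shapes are
    qualitative defaults (see ``_DEFAULT_CLASS_PARAMS``), not ground truth.
    """
    return SimSpec(
        n_subjects=n_subjects,
        class_weights=np.array([0.237, 0.070, 0.226, 0.098, 0.200, 0.169]),
        class_params=_DEFAULT_CLASS_PARAMS.copy(),
        residual_sd=np.full((2, N_VISITS), 2.5),
        dropout_hazard=np.full(6, _DEFAULT_HAZARD),
        membership_logits=_DEFAULT_MEMBERSHIP_LOGITS.copy(),
        covariate_missing_rate=covariate_missing_rate,
        class_names=DEFAULT_CLASS_NAMES,
        seed=seed,
    )
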