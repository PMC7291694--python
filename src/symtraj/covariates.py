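"""Covariate preparation for the class-membership regression.

Three stages, mirroring common practice for auxiliary latent-class
predictors: (1) binarize categorical covariates against the labelled level
(age >= 36, female, bachelor-or-higher, therapist experience cut),
(2) iteratively impute missing entries with random-forest learners
(missForest-style: per-variable fits on all other covariates, stopping when
the change between successive imputations stops decreasing), and
(3) log-transform the heavy-tailed words-per-week rates.

Outcome and class variables are never used as imputation predictors
(information-leakage masking); outcome missingness itself is handled by the
mixture likelihood, not imputed here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .simulate import (AGE_BANDS, EDUCATION_LEVELS, EXPERIENCE_BANDS,
                       GENDERS)

__all__ = [
    "ImputeConfig",
    "ImputationReport",
    "binarize_categoricals",
    "impute_covariates",
    "log_transform_words",
    "prepare_covariates",
    "REGRESSION_COLUMNS",
]

# design-matrix order for the odds-ratio table
REGRESSION_COLUMNS = (
    "age_ge_36", "female", "bachelor_plus", "weeks_in_treatment",
    "log_patient_words", "therapist_exp_ge_10", "orientation_cbt",
    "orientation_third_wave", "orientation_dynamic", "log_therapist_words",
)

_BINARIZE_MAPS = {
    "age_band": ("age_ge_36", {"18-25": 0, "26-35": 0, "36-49": 1, "50+": 1}),
    "gender": ("female", {"Female": 1, "Male": 0}),
    "education": ("bachelor_plus", {"Bachelor Degree or Higher": 1,
                                    "High School Diploma": 0}),
}
# the experience cut is configurable; default >= 10 years vs fewer
_EXPERIENCE_MAPS = {
    "ge_10": {"<5 Years": 0, "5-9 Years": 0, "10+ Years": 1},
    "ge_5": {"<5 Years": 0, "5-9 Years": 1, "10+ Years": 1},
}


def binarize_categoricals(table: pd.DataFrame,
                          experience_cut: str = "ge_10") -> pd.DataFrame:
    """Convert categorical covariates into modal-contrast indicators.

    Missing entries stay missing (imputation happens separately).  Already
    binarized tables pass through unchanged (idempotent).  Unknown category
    labels raise with the list of valid labels.
    """
    out = table.copy()
    maps = dict(_BINARIZE_MAPS)
    if experience_cut not in _EXPERIENCE_MAPS:
        raise ValueError(f"unknown experience_cut {experience_cut!r}; "
                         f"valid: {sorted(_EXPERIENCE_MAPS)}")
    maps["therapist_experience"] = ("therapist_exp_ge_10",
                                    _EXPERIENCE_MAPS[experience_cut])
    mapping_record = {}
    for col, (newcol, mapping) in maps.items():
        if col not in out.columns:
            continue
        vals = out[col]
        observed = vals.dropna()
        unknown = set(observed.unique()) - set(mapping)
        if unknown:
            raise ValueError(
                f"unknown {col} labels {sorted(map(str, unknown))}; "
                f"valid: {sorted(mapping)}")
        out[newcol] = vals.map(mapping)
        out = out.drop(columns=[col])
        mapping_record[col] = {"indicator": newcol, "levels": mapping}
    out.attrs["binarization"] = mapping_record
    return out


@dataclass
class ImputeConfig:
    """Random-forest imputation settings (default 500 trees, 10 sweeps)."""

    n_trees: int = 500
    max_iter: int = 10
    seed: int = 0
    missingness_cap: float = 0.4
    min_oob_improvement: float = 0.0
    exclude_predictors: tuple = ("subject_id",)


@dataclass
class ImputationReport:
    missing_fraction: dict
    n_iterations: int
    stopped_because: str
    change_trace: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"missing_fraction": self.missing_fraction,
                       "n_iterations": self.n_iterations,
                       "stopped_because": self.stopped_because,
                       "change_trace": self.change_trace}, fh, indent=2)


def _is_categorical(series: pd.Series) -> bool:
    s = series.dropna()
    return s.dtype == object or s.nunique() <= 2


def impute_covariates(table: pd.DataFrame,
                      config: Optional[ImputeConfig] = None
                      ) -> tuple[pd.DataFrame, ImputationReport]:
    """Iteratively impute missing covariates with random forests.

    Variables are visited in order of increasing missingness; each gets a
    forest (classifier for categoricals/binaries, regressor otherwise)
    trained on the other covariates' current values and predicted at its
    missing rows.  Sweeps stop when the normalized change between
    successive imputations increases (the previous sweep's values are
    returned, missForest-style) or at ``max_iter``.  Observed entries are
    never altered.  A variable above the missingness cap (default ~40%) or
    all-missing is refused with the per-variable missingness report.
    """
    if config is None:
        config = ImputeConfig()
    out = table.copy()
    predictors = [c for c in out.columns
                  if c not in config.exclude_predictors]
    miss_frac = {c: float(out[c].isna().mean()) for c in predictors}
    targets = [c for c in predictors if miss_frac[c] > 0]
    report = ImputationReport(missing_fraction=miss_frac, n_iterations=0,
                              stopped_because="no missing values")
    if not targets:
        return out, report
    bad = {c: f for c, f in miss_frac.items() if f > config.missingness_cap}
    if bad or any(miss_frac[c] >= 1.0 for c in targets):
        raise ValueError(
            "refusing to impute: variables exceed the missingness cap "
            f"({config.missingness_cap:.0%}): {bad or 'all-missing column'}; "
            f"per-variable missingness: {miss_frac}")

    rng = np.random.default_rng(config.seed)
    targets.sort(key=lambda c: miss_frac[c])
    cat = {c: _is_categorical(out[c]) for c in predictors}
    masks = {c: out[c].isna().to_numpy() for c in targets}

    # initial fill: mode for categoricals, mean otherwise
    work = out[predictors].copy()
    codes: dict[str, dict] = {}
    for c in predictors:
        if cat[c]:
            levels = sorted(work[c].dropna().unique(), key=str)
            codes[c] = {lv: i for i, lv in enumerate(levels)}
            work[c] = work[c].map(codes[c])
    for c in predictors:
        col = work[c]
        if col.isna().any():
            fill = (col.mode().iloc[0] if cat[c] else col.mean())
            work[c] = col.fillna(fill)
    work = work.astype(float)

    def sweep_change(new: pd.DataFrame, old: pd.DataFrame) -> float:
        num = 0.0
        for c in targets:
            m = masks[c]
            a, b = new[c].to_numpy()[m], old[c].to_numpy()[m]
            if cat[c]:
                num += float(np.mean(a != b)) if m.any() else 0.0
            else:
                denom = float(np.var(new[c])) or 1.0
                num += float(np.sum((a - b) ** 2) / (m.sum() * denom))
        return num / len(targets)

    prev = work.copy()
    best = work.copy()
    prev_change = np.inf
    stopped = "max_iter reached"
    it = 0
    for it in range(1, config.max_iter + 1):
        for c in targets:
            m = masks[c]
            X_cols = [p for p in predictors if p != c]
            X = work[X_cols].to_numpy()
            y = work[c].to_numpy()
            seed_i = int(rng.integers(2 ** 31))
            if cat[c]:
                est = RandomForestClassifier(n_estimators=config.n_trees,
                                             random_state=seed_i, n_jobs=1)
            else:
                est = RandomForestRegressor(n_estimators=config.n_trees,
                                            random_state=seed_i, n_jobs=1)
            est.fit(X[~m], y[~m])
            if m.any():
                work.loc[m, c] = est.predict(X[m])
        change = sweep_change(work, prev)
        report.change_trace.append(change)
        if change >= prev_change:
            stopped = "change between sweeps stopped decreasing"
            work = best  # return the previous sweep's imputation
            break
        best = work.copy()
        prev = work.copy()
        prev_change = change
        if change == 0.0:
            stopped = "imputation reached a fixed point"
            break
    report.n_iterations = it
    report.stopped_because = stopped

    for c in targets:
        vals = work[c]
        if cat[c]:
            inv = {v: k for k, v in codes[c].items()}
            vals = vals.round().clip(0, len(inv) - 1).map(inv)
        m = masks[c]
        filled = out[c].copy()
        filled[m] = vals[m]
        out[c] = filled
    return out, report


def log_transform_words(rate, plus_one: bool = True):
    """Monotone log transform of a words/week rate.

    Defaults to log(1 + x) so zero word counts are defined; pure log(x)
    (positive rates only) is available with ``plus_one=False``.
    """
    arr = np.asarray(rate, dtype=float)
    if np.any(arr < 0):
        raise ValueError("word rates must be non-negative")
    if plus_one:
        out = np.log1p(arr)
    else:
        if np.any(arr == 0):
            raise ValueError("plus_one=False requires strictly positive "
                             "rates")
        out = np.log(arr)
    return float(out) if out.ndim == 0 else out


def prepare_covariates(table: pd.DataFrame,
                       impute: Optional[ImputeConfig] = None,
                       experience_cut: str = "ge_10",
                       plus_one: bool = True
                       ) -> tuple[pd.DataFrame, ImputationReport]:
    """Binarize, impute, and log-transform into the regression design.

    Returns a frame with ``subject_id`` plus :data:`REGRESSION_COLUMNS`
    and the imputation report.
    """
    out = binarize_categoricals(table, experience_cut=experience_cut)
    out, report = impute_covariates(out, impute)
    out["log_patient_words"] = log_transform_words(
        out["patient_words_per_week"].to_numpy(), plus_one=plus_one)
    out["log_therapist_words"] = log_transform_words(
        out["therapist_words_per_week"].to_numpy(), plus_one=plus_one)
    keep = ["subject_id", *REGRESSION_COLUMNS]
    missing_cols = [c for c in keep if c not in out.columns]
    if missing_cols:
        raise ValueError(f"covariate table lacks columns: {missing_cols}")
    return out[keep].astype(float), report
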