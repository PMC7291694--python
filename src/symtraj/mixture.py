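"""Parallel-process latent class growth model (LCGA) estimated by EM.

Each of K classes is a pair of fixed quadratic mean curves — one for each
symptom scale — with no within-class growth-factor variance: an observation
is the class curve evaluated at the coded visit time plus independent
Gaussian residual noise.  Residual variances are shared across classes and
(by default) free per outcome and visit.  Missing visits are handled by
marginalizing the likelihood over the unobserved cells (MAR), so subjects
contribute exactly their observed assessments.

Estimation is by an expectation/conditional-maximization sweep: the E-step
computes class responsibilities; the M-step solves, per class and outcome, a
responsibility-weighted (generalized) least-squares fit of the observed
totals on (1, t, t^2), then updates class weights and the pooled residual
variances.  Both conditional M-steps maximize the expected complete-data
log-likelihood, so the observed log-likelihood is non-decreasing across
iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .simulate import PanelDataset, N_VISITS, OUTCOMES

__all__ = [
    "ClassParams",
    "MixtureModel",
    "EMConfig",
    "trajectory_mean",
    "subject_loglik",
    "fit_em",
    "modal_assignment",
    "validate_posterior",
    "simulate_from_model",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _design(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    return np.column_stack([np.ones_like(t), t, t ** 2])


@dataclass(frozen=True)
class ClassParams:
    """Growth parameters of one class: (intercept, slope, quadratic) per
    outcome, plus the class weight."""

    phq: tuple[float, float, float]
    gad: tuple[float, float, float]
    weight: float


@dataclass
class MixtureModel:
    """A fitted (or constructed) K-class parallel-process LCGA.

    ``means`` has shape (K, 2, 3): per class, per outcome (PHQ-9, GAD-7),
    the growth triple on the coded time scale.  ``residual_sd`` has shape
    (2, n_visits) — per outcome per visit, shared across classes.
    """

    weights: np.ndarray
    means: np.ndarray
    residual_sd: np.ndarray
    times: np.ndarray = field(
        default_factory=lambda: np.arange(N_VISITS, dtype=float))
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = True
    restart_index: int = 0
    final_rel_change: float = np.nan
    n_restarts_triggered: int = 0
    var_structure: str = "by_visit"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.residual_sd = np.asarray(self.residual_sd, dtype=float)
        if self.residual_sd.ndim == 1:
            self.residual_sd = np.tile(self.residual_sd[:, None],
                                       (1, len(self.times)))
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_classes(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        K = self.n_classes
        n_var = (2 * len(self.times) if self.var_structure == "by_visit"
                 else 2)
        return 6 * K + (K - 1) + n_var

    @property
    def classes(self) -> list[ClassParams]:
        return [ClassParams(phq=tuple(self.means[c, 0]),
                            gad=tuple(self.means[c, 1]),
                            weight=float(self.weights[c]))
                for c in range(self.n_classes)]

    def cell_means(self) -> np.ndarray:
        """Model-implied means, shape (K, 2, n_visits)."""
        return self.means @ _design(self.times).T

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "residual_sd": self.residual_sd.tolist(),
            "times": self.times.tolist(),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "restart_index": int(self.restart_index),
            "final_rel_change": float(self.final_rel_change),
            "n_restarts_triggered": int(self.n_restarts_triggered),
            "var_structure": self.var_structure,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "MixtureModel":
        return cls(weights=np.asarray(raw["weights"]),
                   means=np.asarray(raw["means"]),
                   residual_sd=np.asarray(raw["residual_sd"]),
                   times=np.asarray(raw["times"]),
                   loglik=raw.get("loglik", np.nan),
                   n_iter=raw.get("n_iter", 0),
                   converged=raw.get("converged", True),
                   restart_index=raw.get("restart_index", 0),
                   var_structure=raw.get("var_structure", "by_visit"))


def trajectory_mean(params, outcome, t):
    """Expected total score i + s*t + q*t^2 for one class and outcome.

    ``params`` may be a ClassParams or a (intercept, slope, quadratic)
    triple; ``outcome`` is "phq9"/"gad7" (ignored for a bare triple).
    """
    if isinstance(params, ClassParams):
        coef = params.phq if outcome == "phq9" else params.gad
    else:
        coef = params
    i, s, q = coef
    t = np.asarray(t, dtype=float)
    out = i + s * t + q * t ** 2
    return float(out) if out.ndim == 0 else out


def _log_density_matrix(model: MixtureModel, Y: np.ndarray,
                        M: np.ndarray) -> np.ndarray:
    """Per-subject, per-class log density over observed cells: (n, K)."""
    mu = model.cell_means()                       # (K, 2, V)
    sd = model.residual_sd                        # (2, V)
    z = (Y[:, None, :, :] - mu[None]) / sd        # (n, K, 2, V)
    cell = -0.5 * z ** 2 - np.log(sd) - 0.5 * _LOG_2PI
    return np.einsum("nkov,nov->nk", cell, M.astype(float))


def subject_loglik(model: MixtureModel, Y: np.ndarray,
                   M: np.ndarray) -> np.ndarray:
    """Log marginal density per subject: log sum_c pi_c f_c(observed cells).

    ``Y`` and ``M`` are (n, 2, n_visits) value and observed-mask arrays (a
    single subject may be passed as (2, n_visits)).  Only observed cells
    contribute; a subject with no observed visit is an error.
    """
    Y = np.asarray(Y, dtype=float)
    M = np.asarray(M, dtype=bool)
    if Y.ndim == 2:
        Y, M = Y[None], M[None]
    if np.any(~M.any(axis=(1, 2))):
        raise ValueError("every subject needs at least one observed visit")
    logd = _log_density_matrix(model, Y, M)
    return logsumexp(logd + np.log(model.weights), axis=1)


@dataclass
class EMConfig:
    """Estimation settings for :func:`fit_em`.

    ``restarts`` counts initializations: the first uses per-subject OLS
    growth coefficients clustered by k-means, the rest random soft
    responsibilities.  Each restart runs ``short_iters`` EM sweeps; the best
    is continued to ``tol`` (relative log-likelihood change) or ``max_iter``.
    """

    tol: float = 1e-6
    max_iter: int = 500
    restarts: int = 20
    short_iters: int = 40
    seed: int = 0
    var_structure: str = "by_visit"  # or "constant"
    weight_floor: Optional[float] = None  # default 1/n
    var_floor: float = 1e-3
    time_coding: str = "index"  # or "weeks"


def modal_assignment(post: np.ndarray) -> np.ndarray:
    """Most-likely class per row; ties break toward the lower class index."""
    post = np.asarray(post, dtype=float)
    return post.argmax(axis=1)


def validate_posterior(post: np.ndarray, atol: float = 1e-10) -> None:
    post = np.asarray(post)
    if np.any(post < -atol) or np.any(post > 1 + atol):
        raise ValueError("posterior entries must lie in [0, 1]")
    if not np.allclose(post.sum(axis=1), 1.0, atol=atol):
        raise ValueError("posterior rows must sum to 1")


def _e_step(model: MixtureModel, Y, M):
    logd = _log_density_matrix(model, Y, M) + np.log(model.weights)
    mx = logd.max(axis=1)
    R = np.exp(logd - mx[:, None])
    norm = R.sum(axis=1)
    ll = mx + np.log(norm)
    R /= norm[:, None]
    return R, float(ll.sum())


def _m_step(model: MixtureModel, Y, M, R, config: EMConfig) -> MixtureModel:
    X = _design(model.times)                       # (V, 3)
    V = len(model.times)
    K = model.n_classes
    Mf = M.astype(float)
    inv_var = 1.0 / model.residual_sd ** 2         # (2, V)

    # growth coefficients: per (class, outcome) GLS of observed totals
    # weighted by responsibility and inverse residual variance
    W0 = np.einsum("nk,nov->kov", R, Mf) * inv_var          # (K, 2, V)
    W1 = np.einsum("nk,nov,nov->kov", R, Mf, Y) * inv_var   # (K, 2, V)
    A = np.einsum("kov,va,vb->koab", W0, X, X)              # (K, 2, 3, 3)
    b = np.einsum("kov,va->koa", W1, X)                     # (K, 2, 3)
    means = np.linalg.solve(A, b[..., None])[..., 0]        # (K, 2, 3)

    mu = means @ X.T                                        # (K, 2, V)
    resid2 = np.einsum("nk,nov,nkov->ov", R, Mf,
                       (Y[:, None] - mu[None]) ** 2)
    counts = Mf.sum(axis=0)                                 # (2, V)
    if config.var_structure == "constant":
        var = resid2.sum(axis=1, keepdims=True) / counts.sum(
            axis=1, keepdims=True)
        var = np.tile(var, (1, V))
    else:
        var = resid2 / counts
    var = np.maximum(var, config.var_floor)

    weights = R.mean(axis=0)
    return MixtureModel(weights=weights, means=means,
                        residual_sd=np.sqrt(var), times=model.times,
                        var_structure=config.var_structure)


class _WeightCollapse(RuntimeError):
    pass


def _run_em(init: MixtureModel, Y, M, config: EMConfig, n_iter: int,
            floor: float):
    model = init
    ll_prev = -np.inf
    rel = np.inf
    it = 0
    for it in range(1, n_iter + 1):
        R, ll = _e_step(model, Y, M)
        new = _m_step(model, Y, M, R, config)
        if np.any(new.weights < floor):
            raise _WeightCollapse
        model = new
        rel = abs(ll - ll_prev) / (abs(ll_prev) + 1e-12)
        if np.isfinite(ll_prev) and rel < config.tol:
            ll_prev = ll
            break
        ll_prev = ll
    R, ll = _e_step(model, Y, M)
    model.loglik = ll
    model.n_iter = it
    model.final_rel_change = rel
    return model, R


def _ols_growth_features(Y, M, X) -> np.ndarray:
    """Per-subject least-squares growth coefficients on observed visits.

    Rank-deficient subjects (fewer observed visits than 3) get the
    minimum-norm solution; the result is only used to seed k-means.
    """
    n = Y.shape[0]
    feats = np.zeros((n, 6))
    # batch subjects sharing a missingness pattern (monotone dropout means
    # only a handful of patterns occur)
    for o in range(2):
        patterns, inverse = np.unique(M[:, o, :], axis=0,
                                      return_inverse=True)
        for pi, pat in enumerate(patterns):
            rows = inverse == pi
            if not pat.any():
                continue
            pinv = np.linalg.pinv(X[pat])            # (3, n_obs)
            feats[rows, 3 * o:3 * o + 3] = Y[rows][:, o, pat] @ pinv.T
    return feats


def _canonical_order(model: MixtureModel) -> np.ndarray:
    """Class order: descending baseline PHQ mean, ties by baseline GAD."""
    mu0 = model.cell_means()[:, :, 0]  # (K, 2) baseline means
    return np.lexsort((-mu0[:, 1], -mu0[:, 0]))


def _relabel(model: MixtureModel, R: np.ndarray):
    order = _canonical_order(model)
    model.weights = model.weights[order]
    model.means = model.means[order]
    return model, R[:, order]


def fit_em(panel: PanelDataset | tuple, K: int,
           config: Optional[EMConfig] = None):
    """Fit a K-class parallel-process LCGA by EM with restarts.

    ``panel`` is a PanelDataset or a pre-extracted ``(Y, mask)`` pair.
    Returns ``(model, posterior)`` where ``posterior`` is the (n, K)
    responsibility matrix under the returned model.  Classes are relabeled
    into the canonical order (descending baseline PHQ-9 mean, ties broken by
    baseline GAD-7 mean) so repeated fits are comparable.  If no restart
    converges the best model is returned with ``converged=False`` and a
    warning, never silently.
    """
    if config is None:
        config = EMConfig()
    if K < 1:
        raise ValueError("K must be >= 1")
    if isinstance(panel, PanelDataset):
        _, Y, M = panel.to_arrays()
        times = (np.arange(len(panel.weeks), dtype=float)
                 if config.time_coding == "index"
                 else np.asarray(panel.weeks, dtype=float))
    else:
        Y, M = panel
        times = np.arange(Y.shape[2], dtype=float)
    Y = np.asarray(Y, dtype=float)
    M = np.asarray(M, dtype=bool)
    n = Y.shape[0]
    if np.any(~M.any(axis=(1, 2))):
        raise ValueError("every subject needs at least one observed visit")
    X = _design(times)
    floor = (config.weight_floor if config.weight_floor is not None
             else 1.0 / n)
    rng = np.random.default_rng(config.seed)

    def init_model(kind: str) -> MixtureModel:
        if kind == "kmeans" and K > 1:
            feats = _ols_growth_features(Y, M, X)
            std = feats.std(axis=0)
            std[std == 0] = 1.0
            km = KMeans(n_clusters=K, n_init=3,
                        random_state=int(rng.integers(2 ** 31)))
            labels = km.fit_predict(feats / std)
            R0 = np.full((n, K), 0.05 / max(K - 1, 1))
            R0[np.arange(n), labels] = 0.95
        else:
            R0 = rng.dirichlet(np.ones(K) * 2.0, size=n)
        base = MixtureModel(weights=np.full(K, 1.0 / K),
                            means=np.zeros((K, 2, 3)),
                            residual_sd=np.ones((2, len(times))) * Y.std(),
                            times=times, var_structure=config.var_structure)
        return _m_step(base, Y, M, R0, config)

    n_restarts = 1 if K == 1 else config.restarts
    candidates = []
    n_collapsed = 0
    attempt = 0
    max_attempts = 3 * n_restarts
    while len(candidates) < n_restarts and attempt < max_attempts:
        kind = "kmeans" if (len(candidates) == 0 and attempt == 0) \
            else "random"
        attempt += 1
        try:
            model, _ = _run_em(init_model(kind), Y, M, config,
                               min(config.short_iters, config.max_iter),
                               floor)
        except _WeightCollapse:
            n_collapsed += 1
            continue
        candidates.append(model)
    if not candidates:
        raise RuntimeError(
            f"all {max_attempts} initializations collapsed a class weight "
            f"below the floor {floor:.2e}; K={K} is likely too large")

    best_i = int(np.argmax([m.loglik for m in candidates]))
    best = candidates[best_i]
    try:
        model, R = _run_em(best, Y, M, config, config.max_iter, floor)
    except _WeightCollapse:
        n_collapsed += 1
        model, R = best, _e_step(best, Y, M)[0]
    model.restart_index = best_i
    model.n_restarts_triggered = n_collapsed
    model.converged = model.final_rel_change < config.tol
    if not model.converged:
        warnings.warn(
            f"EM for K={K} did not reach tol={config.tol:g} within "
            f"{config.max_iter} iterations (final relative change "
            f"{model.final_rel_change:.2e})", RuntimeWarning)
    model, R = _relabel(model, R)
    validate_posterior(R, atol=1e-8)
    return model, R


def simulate_from_model(model: MixtureModel, mask: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Parametric draw from a fitted model at the observed cells of ``mask``.

    Used for the bootstrapped likelihood-ratio test: classes are drawn from
    the fitted weights and observed cells filled with the class mean plus
    Gaussian residual noise (continuous scale, faithful to the fitted
    model).  Unobserved cells are zero.
    """
    n = mask.shape[0]
    classes = rng.choice(model.n_classes, size=n, p=model.weights)
    mu = model.cell_means()[classes]              # (n, 2, V)
    Y = mu + rng.standard_normal(mu.shape) * model.residual_sd
    return np.where(mask, Y, 0.0)
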