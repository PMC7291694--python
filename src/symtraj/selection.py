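"""Class enumeration: information criteria, relative entropy, and
likelihood-ratio tests for K versus K-1 trajectory classes.

The bootstrapped LRT (BLRT) is a parametric bootstrap of 2*(LL_K - LL_{K-1}):
both models are refit to datasets simulated from the fitted (K-1)-class
model with the original missingness pattern, and the p-value is the
finite-sample rank of the observed statistic with the +1 correction.

The Lo-Mendell-Rubin-style adjusted LRT divides the statistic by the
small-sample correction factor c = 1 + ((p_K - p_{K-1}) ln n)^-1 and refers
it to a chi-square approximation of the mixture null; the reference
distribution mode used is always recorded in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import (EMConfig, MixtureModel, fit_em, simulate_from_model,
                      validate_posterior, _run_em, _e_step, _WeightCollapse)
from .simulate import PanelDataset

__all__ = [
    "information_criteria",
    "relative_entropy",
    "LmrResult",
    "lmr_test",
    "BlrtConfig",
    "BlrtResult",
    "blrt",
    "EnumerationConfig",
    "SelectionTable",
    "enumerate_classes",
]


def information_criteria(loglik: float, n_params: int,
                         n_subjects: int) -> tuple[float, float, float]:
    """Return (AIC, BIC, SSBIC).

    AIC = -2 LL + 2p; BIC = -2 LL + p ln n; the sample-size-adjusted BIC
    replaces n by (n + 2) / 24 (Sclove's adjustment).
    """
    if not np.isfinite(loglik):
        raise ValueError("loglik must be finite")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    dev = -2.0 * loglik
    aic = dev + 2.0 * n_params
    bic = dev + n_params * np.log(n_subjects)
    ssbic = dev + n_params * np.log((n_subjects + 2.0) / 24.0)
    return float(aic), float(bic), float(ssbic)


def relative_entropy(post: np.ndarray) -> float:
    """1 minus normalized average posterior classification uncertainty.

    Equals 1 for crisp one-hot posteriors, 0 for uniform rows; undefined
    (ValueError) for a single class.
    """
    post = np.asarray(post, dtype=float)
    validate_posterior(post, atol=1e-8)
    n, K = post.shape
    if K < 2:
        raise ValueError("relative entropy is undefined for K=1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(post > 0, -post * np.log(post), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(K)))


@dataclass(frozen=True)
class LmrResult:
    statistic: float
    adjusted_statistic: float
    p_value: float
    df: int
    correction: float
    mode: str


def lmr_test(model_k: MixtureModel, model_km1: MixtureModel,
             n_subjects: int, mode: str = "wolfe-adjusted-chisq",
             null_draws: Optional[np.ndarray] = None) -> LmrResult:
    """Adjusted likelihood-ratio test of K-1 versus K classes.

    The statistic is 2*(LL_K - LL_{K-1}), floored at zero (a negative value
    indicates a local optimum in the larger model and triggers a warning).
    It is divided by the small-sample correction
    c = 1 + ((p_K - p_{K-1}) ln n)^-1.

    Modes (always recorded in the result, never silently substituted):

    - ``"wolfe-adjusted-chisq"`` (default): chi-square reference with
      df = twice the number of added non-mixing parameters (Wolfe's rule
      for mixture LRTs; here 2 x 6 = 12 per extra class).
    - ``"naive-chisq"``: chi-square with df = p_K - p_{K-1}; known to be
      liberal for mixtures, provided for comparison only.
    - ``"bootstrap"``: empirical p from supplied ``null_draws`` of the
      unadjusted statistic (e.g. the BLRT's bootstrap replicates).
    """
    if model_k.n_classes != model_km1.n_classes + 1:
        raise ValueError("models must differ by exactly one class")
    dp = model_k.n_params - model_km1.n_params
    stat = 2.0 * (model_k.loglik - model_km1.loglik)
    if stat < 0:
        warnings.warn(
            "LL_K below LL_{K-1}: the larger model is at a local optimum; "
            "statistic floored at 0 (restarts advised)", RuntimeWarning)
        stat = 0.0
    c = 1.0 + 1.0 / (dp * np.log(n_subjects))
    adj = stat / c
    n_growth_added = 6  # two outcomes x (intercept, slope, quadratic)
    if mode == "wolfe-adjusted-chisq":
        df = 2 * n_growth_added
        p = float(stats.chi2.sf(adj, df))
    elif mode == "naive-chisq":
        df = dp
        p = float(stats.chi2.sf(adj, df))
    elif mode == "bootstrap":
        if null_draws is None:
            raise ValueError("mode='bootstrap' requires null_draws")
        draws = np.asarray(null_draws, dtype=float)
        df = dp
        p = float((1 + np.sum(draws >= stat)) / (len(draws) + 1))
    else:
        raise ValueError(f"unknown LMR mode {mode!r}")
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return LmrResult(statistic=float(stat), adjusted_statistic=float(adj),
                     p_value=p, df=int(df), correction=float(c), mode=mode)


@dataclass
class BlrtConfig:
    """Settings for the bootstrapped LRT.

    ``restarts`` applies identically to the observed-data fits and the
    bootstrap refits so both are produced by the same optimizer (this keeps
    the bootstrap p-value calibrated).  Bootstrap refits additionally seed
    one initialization from the parent fit.  ``early_stop_alpha`` stops
    replication once the accept/reject decision at that level is settled;
    the reported p is then a conservative partial-rank estimate flagged by
    ``early_stopped``.
    """

    n_bootstrap: int = 99
    restarts: int = 4
    short_iters: int = 30
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0
    early_stop_alpha: Optional[float] = None
    em: EMConfig = field(default_factory=EMConfig)

    def fit_config(self, seed: int) -> EMConfig:
        return replace(self.em, restarts=self.restarts,
                       short_iters=self.short_iters,
                       max_iter=self.max_iter, tol=self.tol, seed=seed)


@dataclass(frozen=True)
class BlrtResult:
    statistic: float
    p_value: float
    n_bootstrap: int
    n_completed: int
    n_exceed: int
    n_failed: int
    early_stopped: bool
    null_draws: np.ndarray

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value <= alpha


def _fit_with_parent(Y, M, K, parent: Optional[MixtureModel],
                     config: EMConfig):
    """Fit K classes, adding the parent's solution as one initialization."""
    model, _ = fit_em((Y, M), K, config)
    if parent is not None and parent.n_classes == K:
        try:
            refit, _ = _run_em(
                MixtureModel(weights=parent.weights.copy(),
                             means=parent.means.copy(),
                             residual_sd=parent.residual_sd.copy(),
                             times=parent.times,
                             var_structure=config.var_structure),
                Y, M, config, config.max_iter, 1.0 / Y.shape[0])
            if refit.loglik > model.loglik:
                model = refit
        except _WeightCollapse:
            pass
    return model


def blrt(panel: PanelDataset | tuple, K: int,
         config: Optional[BlrtConfig] = None,
         fitted_k: Optional[MixtureModel] = None,
         fitted_km1: Optional[MixtureModel] = None) -> BlrtResult:
    """Bootstrapped likelihood-ratio test of K-1 versus K classes.

    Pre-fitted models may be passed to avoid refitting the observed data;
    they must come from the same fit configuration.  Failed bootstrap
    refits are dropped and counted, with a warning if more than 10% drop.
    """
    if K < 2:
        raise ValueError("BLRT requires K >= 2")
    if config is None:
        config = BlrtConfig()
    if isinstance(panel, PanelDataset):
        _, Y, M = panel.to_arrays()
    else:
        Y, M = panel
    rng = np.random.default_rng(config.seed)

    if fitted_km1 is None:
        fitted_km1, _ = fit_em((Y, M), K - 1,
                               config.fit_config(int(rng.integers(2 ** 31))))
    if fitted_k is None:
        fitted_k = _fit_with_parent(Y, M, K, None,
                                    config.fit_config(
                                        int(rng.integers(2 ** 31))))
    observed = max(0.0, 2.0 * (fitted_k.loglik - fitted_km1.loglik))

    draws = []
    n_exceed = 0
    n_failed = 0
    early_stopped = False
    # smallest exceedance count that already forces p > alpha
    stop_at = None
    if config.early_stop_alpha is not None:
        stop_at = int(np.floor(config.early_stop_alpha *
                               (config.n_bootstrap + 1)))
    for b in range(config.n_bootstrap):
        Yb = simulate_from_model(fitted_km1, M, rng)
        seed_b = int(rng.integers(2 ** 31))
        try:
            cfg = config.fit_config(seed_b)
            m0 = _fit_with_parent(Yb, M, K - 1, fitted_km1, cfg)
            m1 = _fit_with_parent(Yb, M, K, fitted_k, cfg)
        except RuntimeError:
            n_failed += 1
            continue
        stat_b = max(0.0, 2.0 * (m1.loglik - m0.loglik))
        draws.append(stat_b)
        if stat_b >= observed:
            n_exceed += 1
        if stop_at is not None and n_exceed > stop_at:
            early_stopped = True
            break
    n_completed = len(draws)
    if n_failed > 0.1 * config.n_bootstrap:
        warnings.warn(f"{n_failed} of {config.n_bootstrap} bootstrap refits "
                      "failed and were dropped", RuntimeWarning)
    p = (1 + n_exceed) / (n_completed + 1) if n_completed else np.nan
    return BlrtResult(statistic=float(observed), p_value=float(p),
                      n_bootstrap=config.n_bootstrap,
                      n_completed=n_completed, n_exceed=n_exceed,
                      n_failed=n_failed, early_stopped=early_stopped,
                      null_draws=np.asarray(draws))


@dataclass
class EnumerationConfig:
    """Settings for :func:`enumerate_classes`."""

    alpha: float = 0.05
    test: str = "lmr"  # or "blrt"
    run_blrt: bool = False
    blrt: BlrtConfig = field(default_factory=BlrtConfig)
    em: EMConfig = field(default_factory=EMConfig)
    lmr_mode: str = "wolfe-adjusted-chisq"


@dataclass
class SelectionTable:
    """Per-K fit indices and LRT results, plus the recommendation."""

    table: pd.DataFrame
    recommended_k: int
    ic_minimizing_k: dict
    models: dict
    posteriors: dict

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"SelectionTable(recommended_k={self.recommended_k}, "
                f"ic_minimizing_k={self.ic_minimizing_k})\n"
                f"{self.table.to_string(index=False)}")


def enumerate_classes(panel: PanelDataset | tuple, K_max: int,
                      config: Optional[EnumerationConfig] = None
                      ) -> SelectionTable:
    """Fit 1..K_max classes and assemble the fit-index table.

    The recommendation scans K upward and stops at the first K whose
    K-vs-(K-1) test (LMR by default, BLRT if configured) is non-significant
    at ``alpha``, recommending K-1; the IC-minimizing K per criterion is
    reported alongside.  The final choice is explicitly the analyst's —
    interpretability is not computed here.  A K that fails to converge is
    flagged in the table and enumeration continues.
    """
    if config is None:
        config = EnumerationConfig()
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    if isinstance(panel, PanelDataset):
        _, Y, M = panel.to_arrays()
    else:
        Y, M = panel
    n = Y.shape[0]
    rng = np.random.default_rng(config.em.seed)

    rows = []
    models: dict[int, MixtureModel] = {}
    posteriors: dict[int, np.ndarray] = {}
    for K in range(1, K_max + 1):
        cfg = replace(config.em, seed=int(rng.integers(2 ** 31)))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                model, post = fit_em((Y, M), K, cfg)
        except RuntimeError as exc:
            rows.append({"K": K, "converged": False, "note": str(exc)})
            continue
        models[K] = model
        posteriors[K] = post
        aic, bic, ssbic = information_criteria(model.loglik, model.n_params,
                                               n)
        row = {
            "K": K, "loglik": model.loglik, "n_params": model.n_params,
            "AIC": aic, "BIC": bic, "SSBIC": ssbic,
            "entropy": relative_entropy(post) if K > 1 else np.nan,
            "converged": model.converged, "note": "",
        }
        if K >= 2 and (K - 1) in models:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                lmr = lmr_test(model, models[K - 1], n, mode=config.lmr_mode)
            row["lmr_stat"] = lmr.adjusted_statistic
            row["lmr_p"] = lmr.p_value
            row["lmr_mode"] = lmr.mode
            if config.run_blrt or config.test == "blrt":
                bcfg = replace(config.blrt, seed=int(rng.integers(2 ** 31)),
                               early_stop_alpha=(config.blrt.early_stop_alpha
                                                 or config.alpha))
                res = blrt((Y, M), K, bcfg, fitted_k=model,
                           fitted_km1=models[K - 1])
                row["blrt_stat"] = res.statistic
                row["blrt_p"] = res.p_value
        rows.append(row)
    table = pd.DataFrame(rows)

    p_col = "lmr_p" if config.test == "lmr" else "blrt_p"
    recommended = 1
    for K in range(2, K_max + 1):
        sub = table[table["K"] == K]
        if sub.empty or p_col not in table.columns:
            break
        p = sub[p_col].iloc[0]
        if not np.isfinite(p) or p >= config.alpha:
            break
        recommended = K
    ic_min = {c: int(table.loc[table[c].idxmin(), "K"])
              for c in ("AIC", "BIC", "SSBIC")
              if c in table.columns and table[c].notna().any()}
    return SelectionTable(table=table, recommended_k=recommended,
                          ic_minimizing_k=ic_min, models=models,
                          posteriors=posteriors)
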