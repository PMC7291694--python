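"""Auxiliary 3-step covariate analysis of latent-class membership.

After the unconditional mixture is fitted, subjects are modally assigned to
classes; the modal label is an error-prone indicator of the true class.
The 3-step ML correction regresses the *true* class on covariates through a
multinomial logit while holding the misclassification probabilities
P(modal = s | true = t) fixed at values derived from the posterior matrix,
so the covariate effects are not attenuated by assignment error.  With a
perfect (identity) classification matrix the likelihood reduces exactly to
a standard multinomial logit of the modal labels on the covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .mixture import modal_assignment, validate_posterior

__all__ = [
    "ClassificationMatrix",
    "ThreeStepResult",
    "classification_matrix",
    "three_step_regression",
    "or_table",
]


@dataclass(frozen=True)
class ClassificationMatrix:
    """Average posterior composition of each modal-assignment group.

    ``q[s, t]`` is the mean posterior probability of class ``t`` among
    subjects modally assigned to class ``s`` — an estimate of
    P(true = t | modal = s).  ``modal_counts[s]`` is the size of modal
    group ``s``.  ``p_modal_given_true`` converts to P(modal = s | true = t)
    by Bayes' rule; that orientation enters the corrected likelihood.
    """

    q: np.ndarray
    modal_counts: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError("classification matrix must be square")
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("classification matrix rows must sum to 1")

    @property
    def n_classes(self) -> int:
        return self.q.shape[0]

    def p_modal_given_true(self) -> np.ndarray:
        """E[s, t] = P(modal = s | true = t), columns sum to 1."""
        joint = (self.modal_counts / self.modal_counts.sum())[:, None] * self.q
        p_true = joint.sum(axis=0)
        return joint / p_true


def classification_matrix(post: np.ndarray,
                          labels: Optional[np.ndarray] = None
                          ) -> ClassificationMatrix:
    """Average posteriors within each modal class.

    Raises if any modal class is empty (the 3-step correction is then
    undefined for that class).  Warns when a diagonal entry falls below
    0.5 — classification too noisy for the assignments to be meaningful.
    """
    post = np.asarray(post, dtype=float)
    validate_posterior(post, atol=1e-8)
    if labels is None:
        labels = modal_assignment(post)
    labels = np.asarray(labels)
    K = post.shape[1]
    q = np.zeros((K, K))
    counts = np.zeros(K)
    for s in range(K):
        members = labels == s
        counts[s] = members.sum()
        if not members.any():
            raise ValueError(f"modal class {s} is empty; cannot form the "
                             "classification-error matrix")
        q[s] = post[members].mean(axis=0)
    q /= q.sum(axis=1, keepdims=True)  # guard floating error only
    if np.any(np.diag(q) < 0.5):
        warnings.warn("classification matrix has a diagonal entry below "
                      "0.5; class assignment is unreliable", RuntimeWarning)
    return ClassificationMatrix(q=q, modal_counts=counts)


@dataclass
class ThreeStepResult:
    """Error-adjusted multinomial-logit estimates.

    ``coef`` has shape (K, p+1): per class (reference row all zero), the
    intercept followed by covariate log-odds versus the reference class.
    ``cov`` is the Wald covariance of the free parameters in row-major
    order over non-reference classes.
    """

    coef: np.ndarray
    cov: np.ndarray
    ref_class: int
    covariate_names: tuple
    class_names: tuple
    loglik: float
    converged: bool
    n_subjects: int
    separation_flags: list = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return self.coef.shape[0]

    def contrast(self, class_a: int, class_b: int) -> np.ndarray:
        """Log-odds of class_a versus class_b (intercept + covariates)."""
        return self.coef[class_a] - self.coef[class_b]

    def summary_frame(self, ref_class: Optional[int] = None,
                      alpha: float = 0.05) -> pd.DataFrame:
        """OR, CI and p per covariate and non-reference class.

        Standard errors for a non-default reference come from the same
        Wald covariance through the contrast's linear map.
        """
        ref = self.ref_class if ref_class is None else ref_class
        if not 0 <= ref < self.n_classes:
            raise ValueError(f"unknown reference class {ref}; valid ids: "
                             f"0..{self.n_classes - 1}")
        z = stats.norm.ppf(1 - alpha / 2)
        p1 = self.coef.shape[1]
        free = [c for c in range(self.n_classes) if c != self.ref_class]
        pos = {c: i for i, c in enumerate(free)}
        rows = []
        for c in range(self.n_classes):
            if c == ref:
                continue
            est = self.contrast(c, ref)
            # variance of (beta_c - beta_ref) from the joint covariance
            L = np.zeros((p1, len(free) * p1))
            if c != self.ref_class:
                L[:, pos[c] * p1:(pos[c] + 1) * p1] = np.eye(p1)
            if ref != self.ref_class:
                L[:, pos[ref] * p1:(pos[ref] + 1) * p1] -= np.eye(p1)
            se = np.sqrt(np.maximum(np.diag(L @ self.cov @ L.T), 0.0))
            for j, name in enumerate(("intercept", *self.covariate_names)):
                if name == "intercept":
                    continue
                est_j, se_j = est[j], se[j]
                pval = 2 * stats.norm.sf(abs(est_j) / se_j) if se_j > 0 \
                    else np.nan
                rows.append({
                    "class": self.class_names[c],
                    "ref": self.class_names[ref],
                    "covariate": name,
                    "estimate": est_j,
                    "se": se_j,
                    "OR": np.exp(est_j),
                    "ci_low": np.exp(est_j - z * se_j),
                    "ci_high": np.exp(est_j + z * se_j),
                    "p": pval,
                })
        return pd.DataFrame(rows)


def _nll_grad(theta: np.ndarray, X: np.ndarray, labels: np.ndarray,
              logE: np.ndarray, K: int, ref: int):
    """Negative log-likelihood and gradient of the corrected model.

    L_i = sum_t P(T=t | x_i) * exp(logE[modal_i, t]) where logE[s, t] =
    log P(modal=s | true=t) is held fixed.
    """
    n, p1 = X.shape
    free = [c for c in range(K) if c != ref]
    B = np.zeros((K, p1))
    B[free] = theta.reshape(len(free), p1)
    eta = X @ B.T
    eta -= eta.max(axis=1, keepdims=True)
    expeta = np.exp(eta)
    P = expeta / expeta.sum(axis=1, keepdims=True)          # (n, K)
    e_obs = np.exp(logE[labels])                            # (n, K)
    L = np.einsum("nk,nk->n", P, e_obs)
    nll = -np.sum(np.log(np.maximum(L, 1e-300)))
    # d logL_i / d eta_iu = P_iu * (e_obs_iu / L_i - 1)
    G = P * (e_obs / L[:, None] - 1.0)                      # (n, K)
    grad_full = G.T @ X                                     # (K, p1)
    grad = -grad_full[free].ravel()
    return nll, grad


def three_step_regression(labels: np.ndarray, Q: ClassificationMatrix,
                          covariates: pd.DataFrame, ref_class: int = 0,
                          covariate_columns: Optional[Sequence[str]] = None,
                          class_names: Optional[Sequence[str]] = None,
                          max_abs_coef: float = 15.0) -> ThreeStepResult:
    """ML 3-step multinomial logit with fixed misclassification offsets.

    ``labels`` are the modal assignments; ``Q`` the classification-error
    matrix from the same posteriors; ``covariates`` a prepared table (one
    row per labelled subject, already imputed/binarized/log-transformed).
    The likelihood is maximized directly (L-BFGS with analytic gradient);
    Wald covariance comes from the numerical Hessian of the negative
    log-likelihood at the optimum.  Perfectly separating covariates are
    detected by runaway coefficients and flagged, with estimates reported
    and CIs marked unstable.
    """
    labels = np.asarray(labels)
    K = Q.n_classes
    if covariate_columns is None:
        covariate_columns = [c for c in covariates.columns
                             if c != "subject_id"]
    Xc = covariates[list(covariate_columns)].to_numpy(dtype=float)
    if len(Xc) != len(labels):
        raise ValueError("covariates must have one row per labelled subject")
    if np.isnan(Xc).any():
        raise ValueError("covariates contain missing values; impute first")
    X = np.column_stack([np.ones(len(Xc)), Xc])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("singular design: covariates are collinear")
    if not 0 <= ref_class < K:
        raise ValueError(f"unknown reference class {ref_class}")
    if class_names is None:
        class_names = tuple(f"class_{c}" for c in range(K))

    # fixed log P(modal | true); zero-probability cells get a large
    # negative offset instead of -inf so the objective stays smooth
    E = Q.p_modal_given_true()
    logE = np.log(np.maximum(E, 1e-12))

    free = [c for c in range(K) if c != ref_class]
    n_free = len(free) * X.shape[1]
    theta0 = np.zeros(n_free)
    res = optimize.minimize(_nll_grad, theta0, args=(X, labels, logE, K,
                                                     ref_class),
                            jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-12,
                                     "gtol": 1e-8})
    theta = res.x
    separation = []
    scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
    theta_mat = theta.reshape(len(free), X.shape[1])
    for i, c in enumerate(free):
        for j, name in enumerate(("intercept", *covariate_columns)):
            if abs(theta_mat[i, j]) * scale[j] > max_abs_coef:
                separation.append((class_names[c], name))
    if separation:
        warnings.warn(
            f"possible separation (runaway coefficients): {separation}; "
            "estimates reported but CIs are unstable", RuntimeWarning)

    # Wald covariance via finite differences of the analytic gradient
    H = np.zeros((n_free, n_free))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(n_free):
        tp = theta.copy()
        tp[j] += h[j]
        tm = theta.copy()
        tm[j] -= h[j]
        _, gp = _nll_grad(tp, X, labels, logE, K, ref_class)
        _, gm = _nll_grad(tm, X, labels, logE, K, ref_class)
        H[:, j] = (gp - gm) / (2 * h[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        separation.append(("<hessian>", "singular"))

    coef = np.zeros((K, X.shape[1]))
    coef[free] = theta_mat
    return ThreeStepResult(coef=coef, cov=cov, ref_class=ref_class,
                           covariate_names=tuple(covariate_columns),
                           class_names=tuple(class_names),
                           loglik=-res.fun, converged=bool(res.success),
                           n_subjects=len(labels),
                           separation_flags=separation)


def or_table(result: ThreeStepResult,
             ref_classes: Optional[Sequence[int]] = None,
             alpha: float = 0.05) -> pd.DataFrame:
    """Odds-ratio table with one block per requested reference class.

    Columns: reference block, class, covariate, OR, 95% CI, p — the
    analogue of a published multinomial-regression table with switchable
    reference classes.  A single-class model yields an empty table with a
    warning.
    """
    if result.n_classes < 2:
        warnings.warn("single-class model: no contrasts to tabulate",
                      RuntimeWarning)
        return pd.DataFrame(columns=["ref", "class", "covariate", "OR",
                                     "ci_low", "ci_high", "p"])
    if ref_classes is None:
        ref_classes = [result.ref_class]
    blocks = []
    for ref in ref_classes:
        frame = result.summary_frame(ref_class=ref, alpha=alpha)
        blocks.append(frame[["ref", "class", "covariate", "OR",
                             "ci_low", "ci_high", "p"]])
    return pd.concat(blocks, ignore_index=True)


def render_or_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of :func:`or_table` output."""
    lines = []
    for ref, block in table.groupby("ref", sort=False):
        lines.append(f"Ref: {ref}")
        for cls, sub in block.groupby("class", sort=False):
            lines.append(f"  vs {cls}")
            for _, r in sub.iterrows():
                lines.append(
                    f"    {r['covariate']:<22s} OR {r['OR']:6.2f}  "
                    f"95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}  "
                    f"p {r['p']:.3g}")
    return "\n".join(lines)
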