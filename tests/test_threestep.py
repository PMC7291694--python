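import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from symtraj.mixture import modal_assignment
from symtraj.threestep import (classification_matrix, or_table,
                               render_or_table, three_step_regression)


def _multinomial_sample(rng, X1, beta):
    """Draw labels from a multinomial logit with coefficient rows beta."""
    eta = X1 @ beta.T
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    u = rng.random(len(X1))
    return (P.cumsum(axis=1) < u[:, None]).sum(axis=1)


def test_classification_matrix_one_hot_is_identity():
    post = np.eye(3)[[0, 1, 2, 2, 0]]
    Q = classification_matrix(post)
    np.testing.assert_allclose(Q.q, np.eye(3))


def test_classification_matrix_hand_example():
    post = np.array([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.2, 0.8]])
    Q = classification_matrix(post)
    np.testing.assert_allclose(Q.q, [[0.85, 0.15], [0.25, 0.75]])
    np.testing.assert_allclose(Q.modal_counts, [2, 2])
    # P(modal | true) columns sum to one
    E = Q.p_modal_given_true()
    np.testing.assert_allclose(E.sum(axis=0), 1.0)


def test_classification_matrix_empty_modal_class_raises():
    post = np.full((5, 2), (0.75, 0.25))
    with pytest.raises(ValueError, match="modal class 1 is empty"):
        classification_matrix(post)


def test_low_diagonal_warns():
    post = np.array([[0.4, 0.3, 0.3], [0.34, 0.33, 0.33],
                     [0.2, 0.5, 0.3], [0.1, 0.2, 0.7]])
    labels = modal_assignment(post)
    with pytest.warns(RuntimeWarning, match="diagonal"):
        classification_matrix(post, labels)


def test_identity_q_equals_standard_multinomial_logit():
    rng = np.random.default_rng(0)
    n, K = 1200, 3
    x = rng.standard_normal((n, 2))
    X1 = np.column_stack([np.ones(n), x])
    beta = np.array([[0, 0, 0], [0.5, 0.8, -0.3], [-0.4, 0.2, 0.6]])
    labels = _multinomial_sample(rng, X1, beta)
    Q = classification_matrix(np.eye(K)[labels], labels)
    res = three_step_regression(labels, Q,
                                pd.DataFrame(x, columns=["x1", "x2"]))
    mn = sm.MNLogit(labels, X1).fit(disp=0)
    np.testing.assert_allclose(res.coef[1:], np.asarray(mn.params).T,
                               atol=1e-4)
    # Wald SEs agree with statsmodels in the error-free case
    ours = res.summary_frame()["se"].to_numpy()
    theirs = np.asarray(mn.bse).T[:, 1:].ravel()
    np.testing.assert_allclose(ours, theirs, rtol=1e-3)


def test_error_adjusted_recovery_of_generating_log_odds():
    rng = np.random.default_rng(1)
    n = 4000
    z = (rng.random(n) < 0.5).astype(float)
    beta = np.array([[0.0, 0.0], [-0.3, 0.8]])
    true = _multinomial_sample(rng, np.column_stack([np.ones(n), z]), beta)
    post = np.where(true[:, None] == np.arange(2), 0.97, 0.03)
    labels = modal_assignment(post)
    Q = classification_matrix(post, labels)
    res = three_step_regression(labels, Q, pd.DataFrame({"z": z}))
    assert res.coef[1, 1] == pytest.approx(0.8, abs=0.15)


def test_reference_class_is_a_pure_reparameterization():
    rng = np.random.default_rng(2)
    n, K = 900, 3
    x = rng.standard_normal((n, 1))
    beta = np.array([[0, 0], [0.4, 0.6], [-0.2, -0.5]])
    true = _multinomial_sample(rng, np.column_stack([np.ones(n), x]), beta)
    post = np.where(true[:, None] == np.arange(K), 0.9, 0.05)
    labels = modal_assignment(post)
    Q = classification_matrix(post, labels)
    cov = pd.DataFrame(x, columns=["x"])
    res0 = three_step_regression(labels, Q, cov, ref_class=0)
    res2 = three_step_regression(labels, Q, cov, ref_class=2)
    for a in range(K):
        for b in range(K):
            np.testing.assert_allclose(res0.contrast(a, b),
                                       res2.contrast(a, b), atol=1e-5)


def test_or_table_blocks_are_mutually_consistent():
    rng = np.random.default_rng(3)
    n, K = 800, 3
    x = rng.standard_normal((n, 1))
    beta = np.array([[0, 0], [0.5, 0.7], [-0.1, -0.4]])
    true = _multinomial_sample(rng, np.column_stack([np.ones(n), x]), beta)
    post = np.where(true[:, None] == np.arange(K), 0.92, 0.04)
    labels = modal_assignment(post)
    Q = classification_matrix(post, labels)
    res = three_step_regression(labels, Q, pd.DataFrame(x, columns=["x"]))
    table = or_table(res, ref_classes=[0, 1])
    b0 = table[(table["ref"] == "class_0") & (table["class"] == "class_1")]
    b1 = table[(table["ref"] == "class_1") & (table["class"] == "class_0")]
    assert b0["OR"].iloc[0] == pytest.approx(1 / b1["OR"].iloc[0])
    assert "OR" in render_or_table(table)
    with pytest.raises(ValueError, match="unknown reference"):
        res.summary_frame(ref_class=7)


def test_single_class_or_table_is_empty_with_warning():
    from symtraj.threestep import ThreeStepResult
    res = ThreeStepResult(coef=np.zeros((1, 2)), cov=np.zeros((0, 0)),
                          ref_class=0, covariate_names=("x",),
                          class_names=("only",), loglik=0.0,
                          converged=True, n_subjects=10)
    with pytest.warns(RuntimeWarning, match="single-class"):
        table = or_table(res)
    assert table.empty


def test_positive_word_coefficient_means_monotone_dose():
    rng = np.random.default_rng(4)
    n = 1500
    w = rng.lognormal(5, 1.5, n)
    logw = np.log1p(w)
    beta = np.array([[0.0, 0.0], [-2.0, 0.4]])
    true = _multinomial_sample(
        rng, np.column_stack([np.ones(n), logw]), beta)
    post = np.eye(2)[true]
    labels = modal_assignment(post)
    Q = classification_matrix(post, labels)
    res = three_step_regression(labels, Q, pd.DataFrame({"logw": logw}))
    coef = res.coef[1, 1]
    assert coef > 0
    # fitted odds of class 1 vs 0 increase with words/week
    grid = np.log1p(np.array([10.0, 100.0, 1000.0]))
    odds = np.exp(res.coef[1, 0] + coef * grid)
    assert np.all(np.diff(odds) > 0)


def test_null_covariate_ci_coverage():
    """With membership independent of the covariate, the nominal 95% Wald
    CI should cover OR = 1 in the vast majority of replicates."""
    rng = np.random.default_rng(5)
    covered = 0
    n_rep = 60
    for _ in range(n_rep):
        n = 600
        z = rng.standard_normal(n)
        true = (rng.random(n) < 0.4).astype(int)
        post = np.where(true[:, None] == np.arange(2), 0.93, 0.07)
        labels = modal_assignment(post)
        Q = classification_matrix(post, labels)
        res = three_step_regression(labels, Q, pd.DataFrame({"z": z}))
        sf = res.summary_frame()
        covered += (sf["ci_low"].iloc[0] <= 1.0 <= sf["ci_high"].iloc[0])
    assert covered >= 0.9 * n_rep


def test_singular_design_and_missing_values_rejected():
    labels = np.array([0, 1, 0, 1])
    post = np.eye(2)[labels]
    Q = classification_matrix(post, labels)
    dup = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
    with pytest.raises(ValueError, match="singular"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            three_step_regression(labels, Q, dup)
    nan = pd.DataFrame({"a": [1.0, np.nan, 3, 4]})
    with pytest.raises(ValueError, match="missing"):
        three_step_regression(labels, Q, nan)
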