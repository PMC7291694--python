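import numpy as np
import pandas as pd
import pytest
from scipy import stats

import symtraj as st
from symtraj.simulate import N_VISITS

from conftest import one_class_spec, two_class_spec


def test_degenerate_noise_free_cohort_is_flat():
    spec = one_class_spec(n=50, seed=1, residual_sd=1e-9,
                          params=((13.0, 0.0, 0.0), (11.0, 0.0, 0.0)))
    panel = st.generate_cohort(spec)
    assert (panel.visits["phq9"] == 13).all()
    assert (panel.visits["gad7"] == 11).all()


def test_zero_dropout_gives_complete_panels():
    spec = one_class_spec(n=80, seed=2, hazard=0.0)
    panel = st.generate_cohort(spec)
    assert (panel.visits.groupby("subject_id").size() == N_VISITS).all()


def test_class_frequencies_match_weights_within_3se():
    spec = two_class_spec(n=10_000, seed=3, weights=(0.7, 0.3))
    panel = st.generate_cohort(spec)
    freq = np.bincount(panel.class_truth, minlength=2) / 10_000
    se = np.sqrt(0.7 * 0.3 / 10_000)
    assert abs(freq[0] - 0.7) < 3 * se


def test_same_seed_same_cohort():
    a = st.generate_cohort(st.default_study_spec(n_subjects=500, seed=9))
    b = st.generate_cohort(st.default_study_spec(n_subjects=500, seed=9))
    pd.testing.assert_frame_equal(a.visits, b.visits)
    pd.testing.assert_frame_equal(a.covariates, b.covariates)
    assert (a.class_truth == b.class_truth).all()


def test_default_spec_class_weights():
    spec = st.default_study_spec()
    assert abs(spec.class_weights.sum() - 1.0) < 1e-12
    # remission group share: recovery + acute recovery
    assert round(spec.class_weights[0] + spec.class_weights[1], 3) == 0.307


def test_default_spec_completion_rate():
    spec = st.default_study_spec(n_subjects=10_000, seed=4,
                                 covariate_missing_rate=0.0)
    panel = st.generate_cohort(spec)
    assert panel.meta["completer_fraction"] == pytest.approx(0.56, abs=0.02)


def test_classwise_visit_means_follow_quadratic_trajectory():
    """Empirical per-class visit means converge to the generating
    quadratic (within 3 SE, allowing rounding variance)."""
    spec = st.default_study_spec(n_subjects=20_000, seed=5,
                                 covariate_missing_rate=0.0)
    panel = st.generate_cohort(spec)
    ids, Y, M = panel.to_arrays()
    t = np.arange(5.0)
    design = np.column_stack([np.ones(5), t, t ** 2])
    mu = spec.class_params @ design.T  # (K, 2, 5)
    var = spec.residual_sd ** 2 + 1.0 / 12.0  # + rounding variance
    for c in range(spec.n_classes):
        members = panel.class_truth == c
        for o in range(2):
            obs = M[members, o, :]
            vals = Y[members, o, :]
            counts = obs.sum(axis=0)
            emp = np.where(counts > 0, (vals * obs).sum(axis=0)
                           / np.maximum(counts, 1), np.nan)
            se = np.sqrt(var[o] / np.maximum(counts, 1))
            assert np.all(np.abs(emp - mu[c, o]) < 3.5 * se)


def test_zero_logits_make_membership_independent_of_covariates():
    """Chi-square test of class vs education non-significant at alpha=0.01
    in at least 18 of 20 seeds."""
    ok = 0
    for seed in range(20):
        spec = st.default_study_spec(n_subjects=800, seed=seed,
                                     covariate_missing_rate=0.0)
        spec.membership_logits[:] = 0.0
        panel = st.generate_cohort(spec)
        table = pd.crosstab(panel.class_truth,
                            panel.covariates["education"])
        _, p, _, _ = stats.chi2_contingency(table)
        ok += p > 0.01
    assert ok >= 18


def test_membership_logits_shift_composition_but_not_margins():
    spec = st.default_study_spec(n_subjects=20_000, seed=6,
                                 covariate_missing_rate=0.0)
    panel = st.generate_cohort(spec)
    freq = np.bincount(panel.class_truth, minlength=6) / 20_000
    assert np.all(np.abs(freq - spec.class_weights) < 0.015)
    educ = (panel.covariates["education"] ==
            "Bachelor Degree or Higher").to_numpy()
    # education favors recovery over elevated chronic by construction
    p_rec = educ[panel.class_truth == 0].mean()
    p_elev = educ[panel.class_truth == 3].mean()
    assert p_rec > p_elev


def test_panel_invariants_hold(default_panel):
    default_panel.validate()
    first = default_panel.visits.groupby("subject_id")["week"].min()
    assert (first == 0).all()


def test_spec_validation_errors():
    spec = one_class_spec()
    spec.class_weights = np.array([0.5, 0.6])
    with pytest.raises(ValueError):
        spec.validate()
    spec = one_class_spec()
    spec.covariate_missing_rate = 0.5
    with pytest.raises(ValueError, match="0.4"):
        spec.validate()
    spec = one_class_spec()
    spec.dropout_hazard[:] = 1.0
    with pytest.raises(ValueError, match="hazard"):
        spec.validate()


def test_spec_yaml_roundtrip(tmp_path):
    spec = st.default_study_spec(n_subjects=123, seed=42)
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    back = st.SimSpec.from_yaml(path)
    np.testing.assert_allclose(back.class_params, spec.class_params)
    np.testing.assert_allclose(back.class_weights, spec.class_weights)
    assert back.seed == 42
    a = st.generate_cohort(spec)
    b = st.generate_cohort(back)
    pd.testing.assert_frame_equal(a.visits, b.visits)


def test_cohort_csv_roundtrip(tmp_path, small_panel):
    vp, cp = tmp_path / "visits.csv", tmp_path / "cov.csv"
    small_panel.write_csv(vp, cp, tmp_path / "meta.yaml")
    visits = pd.read_csv(vp)
    pd.testing.assert_frame_equal(visits, small_panel.visits,
                                  check_dtype=False)
    assert (tmp_path / "meta.yaml").exists()
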