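import numpy as np
import pytest
from hypothesis import settings

import symtraj as st

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


def one_class_spec(n=300, seed=0, residual_sd=4.5,
                   params=((13.4, -1.5, 0.18), (13.4, -1.6, 0.2)),
                   hazard=0.134):
    return st.SimSpec(
        n_subjects=n, class_weights=[1.0],
        class_params=np.array([params]),
        residual_sd=np.full((2, 5), residual_sd),
        dropout_hazard=[hazard],
        membership_logits=np.zeros((1, 3)), seed=seed)


def two_class_spec(n=2000, seed=0, delta=6.0, residual_sd=1.0,
                   weights=(0.6, 0.4), hazard=0.134):
    """Two classes separated by delta*residual_sd in both intercepts."""
    base = np.array([[10.0, -0.8, 0.05], [11.0, -0.9, 0.06]])
    hi = base.copy()
    hi[:, 0] += delta * residual_sd
    return st.SimSpec(
        n_subjects=n, class_weights=list(weights),
        class_params=np.stack([hi, base]),
        residual_sd=np.full((2, 5), residual_sd),
        dropout_hazard=[hazard, hazard],
        membership_logits=np.zeros((2, 3)), seed=seed)


def three_class_spec(n=500, seed=0):
    """Well-separated three-class truth for enumeration studies."""
    return st.SimSpec(
        n_subjects=n, class_weights=[0.45, 0.35, 0.2],
        class_params=np.array([
            [[18.0, -0.4, 0.02], [16.0, -0.3, 0.02]],
            [[13.0, -2.5, 0.30], [12.0, -2.2, 0.25]],
            [[7.0, -1.2, 0.12], [8.0, -1.5, 0.15]]]),
        residual_sd=np.full((2, 5), 2.5),
        dropout_hazard=[0.134] * 3,
        membership_logits=np.zeros((3, 3)), seed=seed)


@pytest.fixture
def small_panel():
    return st.generate_cohort(two_class_spec(n=400, seed=7, delta=4.0,
                                             residual_sd=2.0))


@pytest.fixture
def default_panel():
    return st.generate_cohort(st.default_study_spec(n_subjects=800, seed=3))
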