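import numpy as np
import pytest

from dsccn.synthetic import (
    CanonicalPairSpec,
    SubtypeSpec,
    generate_canonical_pair,
    generate_subtyped_dataset,
)

# Study conditions for the planted-recovery checks: a 300-sample pair with
# 10-feature supports and latent correlation 0.9, and a 528-sample subtyped
# cohort with the 87/31/284/126 class imbalance and class shift = 5 x noise.
PAIR_SPEC = CanonicalPairSpec.with_block_supports(
    s=300, m=100, n=120, k_u=10, k_v=10, u_start=20, v_start=30,
    latent_corr=0.9, noise_sd=0.5, seed=3,
)

SUBTYPED_PAIR = CanonicalPairSpec.with_block_supports(
    s=528, m=120, n=100, k_u=10, k_v=10, u_start=20, v_start=30,
    latent_corr=0.9, noise_sd=0.5, seed=11,
)
SUBTYPED_SPEC = SubtypeSpec(class_sizes=(87, 31, 284, 126), class_shift=2.5, seed=11)


@pytest.fixture(scope="session")
def planted_pair():
    return generate_canonical_pair(PAIR_SPEC)


@pytest.fixture(scope="session")
def subtyped_dataset():
    return generate_subtyped_dataset(SUBTYPED_PAIR, SUBTYPED_SPEC, n_healthy=100)


@pytest.fixture(scope="session")
def small_subtyped_dataset():
    """A lighter 4-class dataset for pipeline plumbing tests."""
    pair = CanonicalPairSpec.with_block_supports(
        s=160, m=40, n=40, k_u=8, k_v=8, u_start=4, v_start=8,
        latent_corr=0.9, noise_sd=0.5, seed=21,
    )
    sub = SubtypeSpec(class_sizes=(40, 30, 50, 40), class_shift=2.5, seed=21)
    return generate_subtyped_dataset(pair, sub, n_healthy=60)


def assert_feasible(fit, X, Y, tol=1e-6):
    """Constraint feasibility every solver fit must satisfy."""
    assert np.linalg.norm(np.asarray(X) @ fit.u) ** 2 <= 1 + tol
    assert np.linalg.norm(np.asarray(Y) @ fit.v) ** 2 <= 1 + tol


def assert_monotone_history(fit, tol=1e-8):
    hist = np.asarray(fit.objective_history)
    assert np.all(np.diff(hist) <= tol)
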