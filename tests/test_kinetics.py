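import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as hst
from scipy.stats import binom

from stochan.kinetics import (
    KineticScheme,
    SchemeError,
    TransitionPair,
    diffusion_matrix,
    drift,
    noise_coefficients,
    rate_matrix,
    steady_state_fractions,
)
from stochan.models import HH_RATES
from stochan.rates import ConstantRate

from conftest import random_scheme, two_state


def _random_inputs(seed, nonneg=True):
    rng = np.random.default_rng(seed)
    scheme = random_scheme(rng)
    x = rng.uniform(0.0 if nonneg else -0.02, 1.0, scheme.n_states)
    x = x / x.sum()
    N = int(rng.integers(1, 10_000))
    return scheme, x, N


# ---------------------------------------------------------------------------
# rate matrix


def test_rate_matrix_two_state_definition():
    A = rate_matrix(two_state(1.0, 2.0), V=0.0)
    assert np.allclose(A, [[-1.0, 1.0], [2.0, -2.0]])


@given(hst.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_rate_matrix_rows_sum_to_zero(seed):
    scheme, _, _ = _random_inputs(seed)
    A = rate_matrix(scheme, V=rng_v(seed))
    assert np.allclose(A.sum(axis=1), 0.0, atol=1e-12)


def rng_v(seed):
    return float(np.random.default_rng(seed).uniform(-90, 90))


def test_rate_matrix_hh_k_matches_hand_assembly(k_scheme):
    # hand-assembled 5x5 chain with multiplicities 4a,3a,2a,a / b,2b,3b,4b
    V = -65.0
    a = HH_RATES["alpha_n"](V)
    b = HH_RATES["beta_n"](V)
    expected = np.zeros((5, 5))
    for i, mult in enumerate((4, 3, 2, 1)):
        expected[i, i + 1] = mult * a
    for j, mult in enumerate((1, 2, 3, 4), start=1):
        expected[j, j - 1] = mult * b
    expected[np.diag_indices(5)] = -expected.sum(axis=1)
    assert np.allclose(rate_matrix(k_scheme, V), expected, rtol=1e-12)


def test_negative_rate_raises():
    bad = KineticScheme(
        n_states=2,
        pairs=[TransitionPair(0, 1, ConstantRate(value=-1.0), ConstantRate(value=1.0))],
        open_state=1,
    )
    with pytest.raises(SchemeError):
        rate_matrix(bad, 0.0)


def test_duplicate_pair_rejected():
    with pytest.raises(SchemeError):
        KineticScheme(
            n_states=2,
            pairs=[
                TransitionPair(0, 1, ConstantRate(value=1.0), ConstantRate(value=1.0)),
                TransitionPair(1, 0, ConstantRate(value=2.0), ConstantRate(value=2.0)),
            ],
            open_state=1,
        )


def test_disconnected_scheme_warns():
    with pytest.warns(UserWarning, match="not connected"):
        KineticScheme(
            n_states=4,
            pairs=[
                TransitionPair(0, 1, ConstantRate(value=1.0), ConstantRate(value=1.0)),
                TransitionPair(2, 3, ConstantRate(value=1.0), ConstantRate(value=1.0)),
            ],
            open_state=3,
        )


def test_pair_canonical_ordering():
    p = TransitionPair(3, 1, ConstantRate(value=2.0), ConstantRate(value=5.0))
    assert (p.i, p.j) == (1, 3)
    assert p.forward(0.0) == 5.0  # swapped with backward
    assert p.backward(0.0) == 2.0


# ---------------------------------------------------------------------------
# drift


def test_drift_detailed_balance_zero():
    d = drift(two_state(1.3, 1.3), np.array([0.5, 0.5]), 0.0)
    assert np.allclose(d, 0.0)


def test_drift_one_way():
    d = drift(two_state(1.0, 0.0), np.array([1.0, 0.0]), 0.0)
    assert np.allclose(d, [-1.0, 1.0])


@given(hst.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_drift_equals_rate_matrix_transpose_product(seed):
    scheme, x, _ = _random_inputs(seed)
    V = rng_v(seed)
    assert np.allclose(
        drift(scheme, x, V), rate_matrix(scheme, V).T @ x, atol=1e-12
    )
    assert abs(drift(scheme, x, V).sum()) < 1e-12


# ---------------------------------------------------------------------------
# diffusion matrix


def test_diffusion_two_state_formula():
    D = diffusion_matrix(two_state(1.0, 1.0), np.array([0.5, 0.5]), 0.0, 10)
    assert np.allclose(D, 0.1 * np.array([[1.0, -1.0], [-1.0, 1.0]]))


@given(hst.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_diffusion_symmetric_conservative_psd(seed):
    scheme, x, N = _random_inputs(seed)
    D = diffusion_matrix(scheme, x, rng_v(seed), N)
    assert np.allclose(D, D.T, atol=1e-14)
    assert np.allclose(D.sum(axis=1), 0.0, atol=1e-12)
    assert np.linalg.eigvalsh(D).min() >= -1e-12


# ---------------------------------------------------------------------------
# noise coefficients (the closed-form square root)


def test_noise_column_counts(k_scheme, na_scheme):
    x_k = np.full(5, 0.2)
    x_na = np.full(8, 0.125)
    assert noise_coefficients(k_scheme, x_k, 0.0, 100).shape == (5, 4)
    assert noise_coefficients(na_scheme, x_na, 0.0, 100).shape == (8, 10)


@given(hst.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_noise_column_structure(seed):
    scheme, x, N = _random_inputs(seed)
    S = noise_coefficients(scheme, x, rng_v(seed), N)
    assert np.allclose(S.sum(axis=0), 0.0, atol=1e-14)
    for k, pair in enumerate(scheme.pairs):
        col = S[:, k]
        nz = np.flatnonzero(col)
        assert set(nz) <= {pair.i, pair.j}
        assert col[pair.i] >= 0.0  # + at the lower-indexed state
        assert col[pair.i] == pytest.approx(-col[pair.j])


@given(hst.integers(0, 100_000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_square_root_identity(seed):
    """Central correctness property: S @ S.T reproduces the diffusion
    matrix for arbitrary schemes and nonnegative state fractions."""
    scheme, x, N = _random_inputs(seed)
    V = rng_v(seed)
    S = noise_coefficients(scheme, x, V, N)
    D = diffusion_matrix(scheme, x, V, N)
    assert np.abs(S @ S.T - D).max() < 1e-12


@given(hst.integers(0, 100_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_square_root_identity_slightly_negative_fractions(seed):
    """The identity survives transiently negative fractions as long as
    every pair flux alpha_ij x_i + alpha_ji x_j stays nonnegative (the
    regime the integrator actually visits)."""
    scheme, x, N = _random_inputs(seed, nonneg=False)
    V = rng_v(seed)
    r = scheme.pair_rates(V)
    flux = np.array(
        [r[k, 0] * x[p.i] + r[k, 1] * x[p.j] for k, p in enumerate(scheme.pairs)]
    )
    assume(np.all(flux >= 0.0))
    S = noise_coefficients(scheme, x, V, N)
    D = diffusion_matrix(scheme, x, V, N)
    assert np.abs(S @ S.T - D).max() < 1e-12


@given(hst.integers(0, 10_000))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_sign_flip_invariance(seed):
    """Flipping the sign of any noise column leaves S S^T unchanged
    (square-root non-uniqueness)."""
    scheme, x, N = _random_inputs(seed)
    V = rng_v(seed)
    S = noise_coefficients(scheme, x, V, N)
    flips = np.where(np.random.default_rng(seed).random(S.shape[1]) < 0.5, -1.0, 1.0)
    assert np.allclose((S * flips) @ (S * flips).T, S @ S.T, atol=1e-14)


# ---------------------------------------------------------------------------
# steady state


def test_steady_state_two_state_closed_form():
    a, b = 1.7, 0.4
    ss = steady_state_fractions(two_state(a, b), 0.0)
    assert np.allclose(ss, [b / (a + b), a / (a + b)], atol=1e-12)


@pytest.mark.parametrize("V", [-90.0, -65.0, 0.0, 70.0])
def test_steady_state_k_is_binomial(k_scheme, V):
    a = HH_RATES["alpha_n"](V)
    b = HH_RATES["beta_n"](V)
    p = a / (a + b)
    ss = steady_state_fractions(k_scheme, V)
    assert np.allclose(ss, binom.pmf(np.arange(5), 4, p), atol=1e-10)
    assert np.abs(drift(k_scheme, ss, V)).max() < 1e-12
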