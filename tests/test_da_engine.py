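import numpy as np
import pytest
from scipy.stats import ks_2samp

from stochan.da_engine import DaState, da_step, simulate_da
from stochan.kinetics import steady_state_fractions
from stochan.mc_engine import simulate_mc
from stochan.models import (
    ChannelPopulation,
    MembraneModel,
    hh_membrane,
    HH_RATES,
)
from stochan.protocols import FreeRun, VoltageClampStep


def test_da_step_matches_hand_written_k_channel_update(k_scheme):
    """Single Euler-Maruyama step against the explicitly written
    five-equation update for the potassium chain (frozen noise draws)."""
    V, dt, N = -20.0, 0.01, 300
    a = HH_RATES["alpha_n"](V)
    b = HH_RATES["beta_n"](V)
    rng = np.random.default_rng(17)
    n = rng.dirichlet(np.ones(5))
    eta = rng.standard_normal(4)
    sq = np.sqrt(dt)
    # per-pair noise amplitudes sqrt((fwd*x_i + bwd*x_j)/N)
    c1 = np.sqrt((4 * a * n[0] + 1 * b * n[1]) / N)
    c2 = np.sqrt((3 * a * n[1] + 2 * b * n[2]) / N)
    c3 = np.sqrt((2 * a * n[2] + 3 * b * n[3]) / N)
    c4 = np.sqrt((1 * a * n[3] + 4 * b * n[4]) / N)
    n0 = n[0] + dt * (b * n[1] - 4 * a * n[0]) + sq * c1 * eta[0]
    n1 = (
        n[1]
        + dt * (4 * a * n[0] + 2 * b * n[2] - (b + 3 * a) * n[1])
        + sq * (-c1 * eta[0] + c2 * eta[1])
    )
    n2 = (
        n[2]
        + dt * (3 * a * n[1] + 3 * b * n[3] - (2 * b + 2 * a) * n[2])
        + sq * (-c2 * eta[1] + c3 * eta[2])
    )
    n3 = (
        n[3]
        + dt * (2 * a * n[2] + 4 * b * n[4] - (3 * b + a) * n[3])
        + sq * (-c3 * eta[2] + c4 * eta[3])
    )
    n4 = 1.0 - (n0 + n1 + n2 + n3)  # redundant state closes the sum

    model = MembraneModel(
        C_m=1.0, g_leak=1e-9, E_leak=0.0,
        populations=[ChannelPopulation(k_scheme, N, 1.0, -77.0)], name="k",
    )
    out = da_step(
        DaState(x=[n], V=V, t=0.0), model, dt, variant="exact",
        voltage_clamp=True, eta=[eta],
    )
    # sign convention: + eta at the lower-indexed state of each pair
    assert np.allclose(out.x[0], [n0, n1, n2, n3, n4], atol=1e-14)
    assert out.x[0].sum() == pytest.approx(1.0, abs=1e-15)


def test_fraction_sum_conserved_over_million_steps(k_clamp_model):
    tr = simulate_da(
        k_clamp_model, VoltageClampStep(total=5000.0, V_hold=-90.0, V_command=70.0),
        dt=0.005, seed=3, record_stride=100_000,
    )
    x = tr.meta["final_state"]
    assert abs(x.sum() - 1.0) < 1e-10


def test_noise_vanishes_in_infinite_channel_limit(k_clamp_model):
    """N -> infinity: the SDE trajectory collapses onto the
    deterministic Euler solution."""
    import dataclasses

    proto = VoltageClampStep(total=10.0, V_hold=-90.0, V_command=70.0)
    big = dataclasses.replace(
        k_clamp_model,
        populations=[dataclasses.replace(k_clamp_model.populations[0], N=int(1e18))],
    )
    noisy = simulate_da(big, proto, dt=0.005, seed=4)
    det = simulate_da(k_clamp_model, proto, dt=0.005, deterministic=True)
    frac_noisy = noisy.open_count[:, 0] / 1e18
    frac_det = det.open_count[:, 0] / 300
    assert np.abs(frac_noisy - frac_det).max() < 1e-6


def test_python_backend_deterministic_equals_kernel(k_clamp_model):
    """With the noise off both backends perform the identical Euler
    recursion; trajectories agree to float round-off."""
    proto = VoltageClampStep(total=2.0, V_hold=-90.0, V_command=70.0)
    kern = simulate_da(k_clamp_model, proto, dt=0.01, deterministic=True)
    py = simulate_da(k_clamp_model, proto, dt=0.01, deterministic=True,
                     backend="python")
    assert np.allclose(kern.open_count, py.open_count, rtol=1e-12, atol=1e-12)


def test_normal_draw_count_per_step_is_pair_count(na_scheme):
    """One Gaussian per transition pair: the sodium population consumes
    exactly 10 draws per step."""

    class CountingRng:
        def __init__(self):
            self.total = 0

        def standard_normal(self, n):
            self.total += n
            return np.zeros(n)

    model = MembraneModel(
        C_m=1.0, g_leak=1e-9, E_leak=0.0,
        populations=[ChannelPopulation(na_scheme, 100, 1.0, 50.0)], name="na",
    )
    rng = CountingRng()
    st = DaState(x=[steady_state_fractions(na_scheme, -65.0)], V=-65.0, t=0.0)
    da_step(st, model, 0.01, rng=rng, voltage_clamp=True)
    assert rng.total == 10


def test_stationary_open_count_binomial_variance(k_clamp_model):
    """Voltage-clamp DA at stationarity: Var(open count) ~ N p (1-p)."""
    p = (HH_RATES["alpha_n"](70.0) / (HH_RATES["alpha_n"](70.0) + HH_RATES["beta_n"](70.0))) ** 4
    tr = simulate_da(
        k_clamp_model, VoltageClampStep(total=40_000.0, V_hold=70.0, V_command=70.0),
        dt=0.005, seed=6, record_stride=1000,  # sample every 5 ms
    )
    samples = tr.open_count[10:, 0]
    n = samples.size
    expect_var = 300 * p * (1 - p)
    ratio = samples.var(ddof=1) / expect_var
    assert abs(ratio - 1.0) < 5 * np.sqrt(2.0 / (n - 1))


def test_da_and_mc_open_count_distributions_agree(k_clamp_model):
    """Two-sample KS between exact-DA and MC open counts at a transient
    and a stationary time point (500 sweeps, alpha = 0.01)."""
    proto = VoltageClampStep(total=8.0, V_hold=-90.0, V_command=70.0)
    probe = [1.0, 8.0]
    data = {"da": {q: [] for q in probe}, "mc": {q: [] for q in probe}}
    for eng, sim in (("da", simulate_da), ("mc", simulate_mc)):
        for k in range(500):
            tr = sim(k_clamp_model, proto, dt=0.005,
                     seed=np.random.SeedSequence((eng == "da", k)))
            for q in probe:
                data[eng][q].append(tr.open_count[np.searchsorted(tr.t, q), 0])
    for q in probe:
        stat = ks_2samp(data["da"][q], data["mc"][q])
        assert stat.pvalue > 0.01, f"t={q}: p={stat.pvalue}"


def test_steady_state_variant_first_step_identical_at_equilibrium(k_clamp_model):
    """Initialised at x_inf(V) under clamp at V, the steady-state
    variant's noise coefficients coincide with the exact ones."""
    proto = VoltageClampStep(total=0.005, V_hold=70.0, V_command=70.0)
    a = simulate_da(k_clamp_model, proto, dt=0.005, seed=11, variant="exact")
    b = simulate_da(k_clamp_model, proto, dt=0.005, seed=11, variant="steady_state")
    assert np.allclose(a.meta["final_state"], b.meta["final_state"], atol=1e-12)


def test_uncoupled_variant_underestimates_transient_variance(k_clamp_model):
    """The uncoupled-particle baseline misses the coupled-channel
    variance peak during the rising phase (panel-style voltage clamp)."""
    from stochan.analysis import ensemble_open_stats

    proto = VoltageClampStep(total=4.0, V_hold=-90.0, V_command=70.0)
    exact = ensemble_open_stats(k_clamp_model, proto, 0.005, 150, seed=21,
                                engine="da", variant="exact")
    unc = ensemble_open_stats(k_clamp_model, proto, 0.005, 150, seed=22,
                              engine="da", variant="uncoupled")
    # average over the rising-phase window (mean between 100 and 200
    # channels) where the coupled variance peak lives
    win_e = (exact.mean > 100) & (exact.mean < 200)
    win_u = (unc.mean > 100) & (unc.mean < 200)
    assert unc.var[win_u].mean() < 0.9 * exact.var[win_e].mean()


def test_divergence_is_flagged_and_truncated():
    """An unstable Euler step (g dt / C >> 2) blows the voltage up; the
    trace is flagged and truncated instead of filling with NaN."""
    model = MembraneModel(C_m=1.0, g_leak=200.0, E_leak=0.0, populations=[],
                          name="unstable")
    tr = simulate_da(model, FreeRun(total=60.0), dt=0.1, V0=1.0)
    assert tr.diverged
    assert np.isfinite(tr.V).all()
    assert tr.meta["diverged_step"] is not None


def test_hh_model_spontaneous_spikes_stochastic_but_not_deterministic():
    """Finite channel numbers produce spontaneous action potentials
    that the deterministic limit lacks."""
    from stochan.analysis import detect_spikes

    model = hh_membrane(300)  # few channels -> vigorous spontaneous firing
    tr = simulate_da(model, FreeRun(total=5000.0), dt=0.01, seed=30,
                     record_stride=10)
    assert detect_spikes(tr.t, tr.V, 0.0).size >= 3
    det = simulate_da(model, FreeRun(total=5000.0), dt=0.01, deterministic=True,
                      record_stride=10)
    assert detect_spikes(det.t, det.V, 0.0).size == 0
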