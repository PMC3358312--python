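"""Benchmark protocols and their analysis fits.

Three analyses probe whether a stochastic engine reproduces channel
noise correctly:

* **Nonstationary noise analysis** (voltage clamp).  Across an
  ensemble of sweeps the variance of the open-channel count at each
  time obeys ``var = i * mean - mean^2 / N`` for N independent binary
  channels with unit single-channel amplitude ``i``; fitting the
  variance-vs-mean relation recovers ``(i, N)``.  The fit is performed
  on mean-binned pairs (classical noise-analysis practice) so that the
  long stationary tail of the record does not swamp the informative
  rising phase; use ``n_bins=None`` for a raw per-time-point fit.
* **Firing efficiency** (current pulse).  The fraction of trials
  firing vs stimulus amplitude is fit with a cumulative Gaussian,
  yielding a threshold (amplitude of 0.5 firing probability) and a
  spread sigma that measures how much channel noise flattens the
  input/output relation.
* **ISI distribution** (free run).  Spontaneous spike trains are
  summarised by the interspike-interval histogram, fit by an
  exponential decay with a refractory dead time; the first two
  histogram bins are excluded from the fit (they deviate from the
  exponential trend for membrane-resonance reasons unrelated to the
  simulation algorithm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import erf

from .da_engine import simulate_da
from .mc_engine import simulate_mc
from .models import MembraneModel
from .protocols import CurrentPulse, FreeRun, Protocol
from .trace import EnsembleStats, _Welford

__all__ = [
    "NoiseFit",
    "FECurveFit",
    "ISIFit",
    "simulate",
    "ensemble_open_stats",
    "fit_noise",
    "run_noise_analysis",
    "detect_spikes",
    "run_firing_efficiency",
    "fit_fe_curve",
    "fit_isi",
    "spontaneous_firing",
]


def simulate(engine: str, model, protocol, dt, seed, variant="exact", **kw):
    """Dispatch to the MC or DA engine by name."""
    if engine == "mc":
        return simulate_mc(model, protocol, dt, seed=seed, **kw)
    if engine == "da":
        return simulate_da(model, protocol, dt, seed=seed, variant=variant, **kw)
    raise ValueError(f"unknown engine {engine!r} (expected 'mc' or 'da')")


def _sweep_seed(seed: int, sweep: int) -> np.random.SeedSequence:
    # one independent stream per sweep, reproducible under any execution order
    return np.random.SeedSequence((int(seed), int(sweep)))


def ensemble_open_stats(
    model: MembraneModel,
    protocol: Protocol,
    dt: float,
    n_sweeps: int,
    seed: int = 0,
    engine: str = "da",
    variant: str = "exact",
    record_stride: int = 1,
    population: int = 0,
    n_groups: int = 0,
    **kw,
) -> EnsembleStats:
    """Per-time-point mean and unbiased variance of the open-channel
    count over ``n_sweeps`` independent sweeps (streaming; sweep k uses
    the stream seeded by ``(seed, k)``).

    With ``n_groups > 0`` the sweeps are additionally split round-robin
    into that many disjoint groups and per-group statistics are kept
    (``meta["groups"]``); downstream fits use them for batch-means
    standard errors that remain valid despite the strong time
    correlation of ensemble variance estimates.
    """
    acc = _Welford()
    groups = [_Welford() for _ in range(n_groups)]
    t = None
    n_div = 0
    for k in range(n_sweeps):
        tr = simulate(
            engine, model, protocol, dt, _sweep_seed(seed, k),
            variant=variant, record_stride=record_stride, **kw,
        )
        if tr.diverged:
            n_div += 1
            continue
        t = tr.t
        x = tr.open_count[:, population]
        acc.add(x)
        if n_groups:
            groups[k % n_groups].add(x)
    if acc.n < 2:
        raise ValueError("need at least 2 non-diverged sweeps")
    return EnsembleStats(
        t=t,
        mean=acc.mean,
        var=acc.variance(),
        n_sweeps=acc.n,
        meta={
            "engine": engine,
            "variant": variant,
            "n_diverged": n_div,
            "groups": [
                (g.mean, g.variance()) for g in groups if g.n >= 2
            ],
        },
    )


# ---------------------------------------------------------------------------
# nonstationary noise analysis


@dataclass
class NoiseFit:
    """Result of the variance-vs-mean fit ``var = i*mean - mean^2/N``."""

    i: float
    N: float
    i_se: float  # curve-fit standard errors (optimistic: binned
    N_se: float  # residuals are strongly time-correlated)
    r_squared: float
    fit_mean: np.ndarray  # points the fit used (binned unless n_bins=None)
    fit_var: np.ndarray
    n_sweeps: int = 0
    i_se_ens: float = np.nan  # batch-means (sweep-group) standard errors;
    N_se_ens: float = np.nan  # the honest ensemble-level uncertainty
    meta: dict = field(default_factory=dict)


def _noise_curve(m, i, N):
    return i * m - m * m / N


def fit_noise(mean: np.ndarray, var: np.ndarray, n_bins: int | None = 100) -> NoiseFit:
    """Least-squares fit of the noise-analysis parabola.

    With ``n_bins`` set (default), the per-time (mean, variance) pairs
    are averaged in equal-width bins along the mean axis before
    fitting, the standard way to weight the full trajectory rather
    than wherever the protocol dwells longest.
    """
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    if mean.size < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(var) == 0.0:
        raise ValueError("degenerate (constant) variance; cannot fit")
    if n_bins is not None:
        edges = np.linspace(mean.min(), mean.max(), n_bins + 1)
        which = np.clip(np.digitize(mean, edges) - 1, 0, n_bins - 1)
        cnt = np.bincount(which, minlength=n_bins)
        ok = cnt > 0
        m_fit = np.bincount(which, weights=mean, minlength=n_bins)[ok] / cnt[ok]
        v_fit = np.bincount(which, weights=var, minlength=n_bins)[ok] / cnt[ok]
    else:
        m_fit, v_fit = mean, var
    # initialisation: slope at the origin ~ i, parabola apex at i*N/2
    low = m_fit <= np.quantile(m_fit, 0.2)
    denom = np.sum(m_fit[low] ** 2)
    i0 = float(np.sum(m_fit[low] * v_fit[low]) / denom) if denom > 0 else 1.0
    if not np.isfinite(i0) or i0 <= 0:
        i0 = 1.0
    m_apex = m_fit[np.argmax(v_fit)]
    N0 = max(2.0 * m_apex / i0, 1.05 * m_fit.max() / i0)
    popt, pcov = curve_fit(_noise_curve, m_fit, v_fit, p0=[i0, N0], maxfev=20000)
    resid = v_fit - _noise_curve(m_fit, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((v_fit - v_fit.mean()) ** 2))
    se = np.sqrt(np.diag(pcov))
    return NoiseFit(
        i=float(popt[0]),
        N=float(popt[1]),
        i_se=float(se[0]),
        N_se=float(se[1]),
        r_squared=1.0 - ss_res / ss_tot,
        fit_mean=m_fit,
        fit_var=v_fit,
    )


def run_noise_analysis(
    model: MembraneModel,
    protocol: Protocol,
    n_sweeps: int,
    dt: float,
    seed: int = 0,
    engine: str = "da",
    variant: str = "exact",
    n_bins: int | None = 100,
    record_stride: int = 1,
    n_groups: int = 10,
) -> NoiseFit:
    """Voltage-clamp ensemble + noise-analysis fit, end to end.

    Besides the curve-fit standard errors, batch-means SEs are computed
    by refitting disjoint sweep groups (``n_groups``); these absorb the
    time correlation of the ensemble statistics and are the errors to
    use when judging consistency with a known channel count.
    """
    stats = ensemble_open_stats(
        model, protocol, dt, n_sweeps, seed=seed, engine=engine,
        variant=variant, record_stride=record_stride, n_groups=n_groups,
    )
    fit = fit_noise(stats.mean, stats.var, n_bins=n_bins)
    fit.n_sweeps = stats.n_sweeps
    group_fits = []
    for g_mean, g_var in stats.meta.get("groups", []):
        try:
            group_fits.append(fit_noise(g_mean, g_var, n_bins=n_bins))
        except (ValueError, RuntimeError):
            continue
    if len(group_fits) >= 3:
        g = len(group_fits)
        fit.i_se_ens = float(np.std([f.i for f in group_fits], ddof=1) / np.sqrt(g))
        fit.N_se_ens = float(np.std([f.N for f in group_fits], ddof=1) / np.sqrt(g))
    stats.meta.pop("groups", None)  # free the per-group arrays
    fit.meta = {"engine": engine, "variant": variant, "stats": stats}
    return fit


# ---------------------------------------------------------------------------
# spike detection and firing efficiency


def detect_spikes(t: np.ndarray, v: np.ndarray, threshold: float) -> np.ndarray:
    """Times at which the voltage reaches or surpasses ``threshold``
    from below (one event per upward crossing; re-arming requires the
    trace to fall back under the threshold)."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    above = v >= threshold
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        idx = np.concatenate([[0], idx])
    return t[idx]


@dataclass
class FECurveFit:
    """Cumulative-Gaussian fit of firing efficiency vs amplitude:
    ``FE(a) = (1 + erf((a - threshold)/(sigma sqrt 2)))/2``."""

    threshold: float
    sigma: float
    threshold_se: float
    sigma_se: float
    r_squared: float


def run_firing_efficiency(
    model: MembraneModel,
    amplitudes,
    n_trials: int,
    dt: float,
    seed: int = 0,
    engine: str = "da",
    variant: str = "exact",
    threshold: float = 80.0,
    pulse_width: float = 0.1,
    total: float = 1.0,
    record_stride: int = 1,
) -> pd.DataFrame:
    """Firing efficiency and firing-time statistics per amplitude.

    Each trial is an independent ``total``-ms run with a
    ``pulse_width``-ms pulse at onset 0; the firing time is the first
    threshold crossing, and trials without a crossing count only in
    the denominator.  Returns a DataFrame with columns amplitude,
    n_trials, n_fired, fe, ft_mean, ft_var, n_diverged.
    """
    from .kinetics import steady_state_fractions
    from .models import resting_potential

    # resting initial condition computed once, reused across trials
    v_rest = resting_potential(model)
    x_rest = (
        None  # the uncoupled variant rewrites the populations
        if variant == "uncoupled"
        else [steady_state_fractions(p.scheme, v_rest) for p in model.populations]
    )
    rows = []
    for a_idx, amp in enumerate(np.asarray(amplitudes, dtype=float)):
        proto = CurrentPulse(total=total, amplitude=amp, onset=0.0, width=pulse_width)
        times = []
        n_div = 0
        for k in range(n_trials):
            tr = simulate(
                engine, model, proto, dt,
                np.random.SeedSequence((int(seed), a_idx, k)),
                variant=variant, record_stride=record_stride,
                V0=v_rest, x0=x_rest,
            )
            if tr.diverged:
                n_div += 1
                continue
            sp = detect_spikes(tr.t, tr.V, threshold)
            if sp.size:
                times.append(sp[0])
        times = np.asarray(times)
        rows.append(
            {
                "amplitude": amp,
                "n_trials": n_trials - n_div,
                "n_fired": times.size,
                "fe": times.size / max(n_trials - n_div, 1),
                "ft_mean": times.mean() if times.size else np.nan,
                "ft_var": times.var(ddof=1) if times.size > 1 else np.nan,
                "n_diverged": n_div,
            }
        )
    return pd.DataFrame(rows)


def _fe_curve(a, th, sigma):
    return 0.5 * (1.0 + erf((a - th) / (sigma * np.sqrt(2.0))))


def fit_fe_curve(amplitudes, fe_values) -> FECurveFit:
    """Fit FE(amplitude) with the cumulative Gaussian; needs data that
    actually bracket the transition."""
    a = np.asarray(amplitudes, dtype=float)
    fe = np.asarray(fe_values, dtype=float)
    if a.size < 4:
        raise ValueError("need at least 4 amplitude levels")
    if fe.max() <= 0.0 or fe.min() >= 1.0 or np.ptp(fe) == 0.0:
        raise ValueError("firing-efficiency data do not bracket the transition")
    order = np.argsort(a)
    a_s, fe_s = a[order], fe[order]
    th0 = float(np.interp(0.5, fe_s, a_s))
    s0 = max(float(np.interp(0.84, fe_s, a_s) - np.interp(0.16, fe_s, a_s)) / 2.0,
             0.1 * (a_s[-1] - a_s[0]) / a_s.size)
    popt, pcov = curve_fit(
        _fe_curve, a, fe, p0=[th0, s0],
        bounds=([-np.inf, 1e-12], [np.inf, np.inf]), maxfev=20000,
    )
    resid = fe - _fe_curve(a, *popt)
    ss_tot = float(np.sum((fe - fe.mean()) ** 2))
    se = np.sqrt(np.diag(pcov))
    return FECurveFit(
        threshold=float(popt[0]),
        sigma=float(popt[1]),
        threshold_se=float(se[0]),
        sigma_se=float(se[1]),
        r_squared=1.0 - float(np.sum(resid**2)) / ss_tot,
    )


# ---------------------------------------------------------------------------
# interspike intervals


@dataclass
class ISIFit:
    """Exponential-decay-with-dead-time fit of the normalised ISI
    density: ``f(t) = rate * exp(-rate (t - t0))`` for ``t >= t0``."""

    rate: float  # ms^-1
    t0: float  # refractory period, ms
    rate_se: float
    t0_se: float
    r_squared: float
    bin_edges: np.ndarray
    density: np.ndarray
    excluded_bins: int
    n_isi: int

    @property
    def tau(self) -> float:
        """Decay time constant (ms)."""
        return 1.0 / self.rate


def fit_isi(
    spike_times=None,
    bin_width: float = 10.0,
    isis=None,
    exclude_bins: int = 2,
    min_isi: int = 50,
    amplitude: str = "tied",
) -> ISIFit:
    """Histogram + fit of the interspike-interval distribution.

    ``amplitude="tied"`` fits the normalised form
    ``rate*exp(-rate(t-t0))``; ``"free"`` fits ``A*exp(-rate*t)`` and
    reports ``t0 = log(A/rate)/rate``.  The first ``exclude_bins``
    histogram bins are excluded from the fit (never from the
    histogram).
    """
    if isis is None:
        st = np.sort(np.asarray(spike_times, dtype=float))
        isis = np.diff(st)
    isis = np.asarray(isis, dtype=float)
    if isis.size < min_isi:
        raise ValueError(f"need >= {min_isi} ISIs for a stable fit, got {isis.size}")
    edges = np.arange(0.0, isis.max() + bin_width, bin_width)
    density, edges = np.histogram(isis, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sel = np.arange(centers.size) >= exclude_bins
    r0 = 1.0 / isis.mean()
    t0_0 = max(float(isis.min()), 1e-3)
    if amplitude == "tied":

        def f(t, rate, t0):
            return np.where(t >= t0, rate * np.exp(-rate * (t - t0)), 0.0)

        popt, pcov = curve_fit(
            f, centers[sel], density[sel], p0=[r0, t0_0], maxfev=20000
        )
        rate, t0 = popt
        se = np.sqrt(np.diag(pcov))
        rate_se, t0_se = se
    elif amplitude == "free":

        def f(t, A, rate):
            return A * np.exp(-rate * t)

        popt, pcov = curve_fit(
            f, centers[sel], density[sel], p0=[r0 * np.exp(r0 * t0_0), r0],
            maxfev=20000,
        )
        A, rate = popt
        t0 = float(np.log(A / rate) / rate)
        se = np.sqrt(np.diag(pcov))
        rate_se, t0_se = se[1], np.nan
    else:
        raise ValueError("amplitude must be 'tied' or 'free'")
    resid = density[sel] - f(centers[sel], *popt)
    ss_tot = float(np.sum((density[sel] - density[sel].mean()) ** 2))
    return ISIFit(
        rate=float(rate),
        t0=float(t0),
        rate_se=float(rate_se),
        t0_se=float(t0_se),
        r_squared=1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan,
        bin_edges=edges,
        density=density,
        excluded_bins=exclude_bins,
        n_isi=int(isis.size),
    )


def spontaneous_firing(
    model: MembraneModel,
    duration: float,
    dt: float,
    seed: int = 0,
    engine: str = "da",
    variant: str = "exact",
    threshold: float = 0.0,
    record_stride: int | None = None,
) -> dict:
    """Free run without stimulus; returns spike times and mean rate.

    ``record_stride`` defaults to sampling the voltage every <= 0.1 ms,
    ample for action-potential detection.
    """
    if record_stride is None:
        record_stride = max(1, int(round(0.1 / dt)))
    tr = simulate(
        engine, model, FreeRun(total=duration), dt, seed,
        variant=variant, record_stride=record_stride,
    )
    spikes = detect_spikes(tr.t, tr.V, threshold)
    sim_time = tr.t[-1] if tr.t.size else 0.0
    return {
        "spike_times": spikes,
        "n_spikes": int(spikes.size),
        "duration": sim_time,
        "rate_hz": 1000.0 * spikes.size / sim_time if sim_time > 0 else np.nan,
        "diverged": tr.diverged,
        "trace": tr,
    }
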