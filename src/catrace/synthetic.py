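"""Synthetic fixture generation with exact ground truth.

Emulates ratiometric (fura-2 style) calcium recordings: ~120 s at 2 samples/s
with the stimulus at ~10 s, a baseline drift (saturating exponential plus
linear, optionally two-phase), a single transient response, an optional train
of oscillatory bumps, i.i.d. Gaussian noise, and intermittent high-amplitude
noise spikes.

Every generated trace comes with a :class:`GroundTruth` whose kinetic
parameters are computed from the generating formulas by fine-grid brute
force, never by the analysis pipeline, so recovery experiments compare two
independent routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .drift import DriftParams, global_drift
from .io import Trace
from .transient import (ActivationParams, ResponseParams, TRMetrics,
                        activation_model, inflection_time, response_model)

_TINY = 1e-12


@dataclass
class OscSpec:
    period: float = 12.0        # s between bump centers
    amplitude: float = 0.5      # bump height (a.u.); well above the 6-sigma
                                # deviation threshold at the stock noise level
    n_cycles: int = 6
    jitter_sd: float = 0.0      # s, Gaussian jitter of bump centers
    fwhm: float = 3.0           # s
    start: float = 40.0         # s, first bump center


@dataclass
class SpikeSpec:
    count: int = 5
    amplitude_sigma: float = 8.0   # in units of noise_sd
    sign: int = 1


@dataclass
class FixtureSpec:
    duration: float = 120.0
    dt: float = 0.5                # 2 samples per second
    stimulus_time: float = 10.0
    drift: DriftParams = field(default_factory=DriftParams)
    tr: ResponseParams | None = None
    osc: OscSpec | None = None
    noise_sd: float = 0.0
    spike: SpikeSpec | None = None
    seed: int = 0


@dataclass
class GroundTruth:
    drift: DriftParams
    tr: ResponseParams | None
    tr_metrics: TRMetrics | None
    osc_times: np.ndarray
    osc_height: float
    osc_fwhm: float
    spike_idx: np.ndarray
    noise_sd: float
    osc_truncated: bool = False


def default_response(
    t_on: float = 12.0,
    amplitude: float = 1.0,
    beta: float = 2.0,
    n_act: float = 3.0,
    rise_extent: float = 6.0,
    gamma: float = 15.0,
    n_de: float = 2.5,
    t_end: float = 120.0,
) -> ResponseParams:
    """A realistic single-transient parameter set for fixtures.

    The deactivation amplitude is tied to the activation value at the
    switch time so the piecewise model is near-continuous before the Hermite
    junction smooths it.
    """
    act = ActivationParams(t_on=t_on, A_act=amplitude, beta=beta, n_act=n_act, m_act=0.0)
    t_de = t_on + rise_extent
    a_de = float(activation_model(t_de - t_on, act))
    return ResponseParams(activation=act, t_de=t_de, sigma_act=0.25 * rise_extent,
                          sigma_de=0.2 * gamma, A_de=a_de, gamma=gamma, n_de=n_de,
                          t_end=t_end)


# ---------------------------------------------------------------------------
# ground-truth metrics by brute force on the generating model
# ---------------------------------------------------------------------------

def model_tr_metrics(rp: ResponseParams, grid_step: float = 1e-3) -> TRMetrics:
    """Kinetic parameters of the noise-free generating response.

    Brute-force on a fine grid: crossings by linear interpolation, AUC by the
    trapezoidal rule, the deactivation inflection from its closed form, and
    tau_decay by a least-squares mono-exponential fit to the model tail.
    """
    p = rp.activation
    tg = np.arange(p.t_on, rp.t_end + grid_step, grid_step)
    g = np.atleast_1d(response_model(tg, rp))
    i_peak = int(np.argmax(g))
    amp = float(g[i_peak])

    def cross(level, lo, hi, direction):
        seg = g[lo:hi + 1]
        if direction > 0:
            hits = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
        else:
            hits = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
        if hits.size == 0:
            return None
        a = lo + hits[0]
        y0, y1 = g[a], g[a + 1]
        frac = (level - y0) / (y1 - y0) if abs(y1 - y0) > _TINY else 0.0
        return tg[a] + frac * (tg[a + 1] - tg[a])

    t10 = cross(0.1 * amp, 0, i_peak, +1)
    t90 = cross(0.9 * amp, 0, i_peak, +1)
    h1 = cross(0.5 * amp, 0, i_peak, +1)
    h2 = cross(0.5 * amp, i_peak, g.size - 1, -1)
    rho = inflection_time(rp.t_de, rp.gamma, rp.n_de)

    tail = tg > rho
    tau = np.nan
    if tail.sum() >= 10:
        y = g[tail]
        tt = tg[tail] - rho

        def r(v):
            return v[0] * np.exp(-tt / v[1]) - y

        sol = least_squares(r, np.array([max(y[0], _TINY), max((rp.t_end - rho) / 3.0, 1.0)]),
                            bounds=([0.0, 1e-3], [np.inf, 1e5]), max_nfev=200)
        tau = float(sol.x[1])

    return TRMetrics(
        t_onset=float(p.t_on),
        t_10_90=(t90 - t10) if (t10 is not None and t90 is not None) else np.nan,
        amplitude=amp,
        auc=float(np.trapezoid(g, tg)),
        fwhm=(h2 - h1) if (h1 is not None and h2 is not None) else np.nan,
        rho=float(rho),
        tau_decay=tau,
    )


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------

def generate_trace(spec: FixtureSpec, trace_id: str = "synthetic") -> tuple[Trace, GroundTruth]:
    """Build one noisy trace and its exact ground truth.

    F = drift + response + oscillation bumps + N(0, noise_sd), with optional
    spikes added at uniformly drawn clean sample indices.  A fixed seed gives
    a bit-identical trace.
    """
    if spec.dt <= 0:
        raise ValueError("dt must be positive")
    times = np.arange(0.0, spec.duration, spec.dt)
    if times.size < 20:
        raise ValueError("fixture too short (need at least 20 samples)")
    rng = np.random.default_rng(spec.seed)

    f_true = np.asarray(global_drift(times, spec.drift), dtype=float).copy()
    tr = spec.tr
    tr_metrics = None
    if tr is not None:
        tr = replace(tr, t_end=float(times[-1]))
        f_true = f_true + np.atleast_1d(response_model(times, tr))
        tr_metrics = model_tr_metrics(tr)

    osc_times = np.zeros(0)
    truncated = False
    if spec.osc is not None:
        o = spec.osc
        centers = o.start + o.period * np.arange(o.n_cycles)
        if o.jitter_sd > 0:
            centers = centers + rng.normal(0.0, o.jitter_sd, centers.size)
        keep = centers < spec.duration - 2.0 * spec.dt
        truncated = bool(np.any(~keep))
        osc_times = np.sort(centers[keep])
        sd = o.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        for c in osc_times:
            f_true = f_true + o.amplitude * np.exp(-((times - c) ** 2) / (2.0 * sd ** 2))

    F = f_true + (rng.normal(0.0, spec.noise_sd, times.size) if spec.noise_sd > 0 else 0.0)

    spike_idx = np.zeros(0, dtype=int)
    if spec.spike is not None and spec.spike.count > 0:
        lo, hi = 2, times.size - 2
        spike_idx = np.sort(rng.choice(np.arange(lo, hi), size=spec.spike.count,
                                       replace=False))
        F = F.copy()
        F[spike_idx] += spec.spike.sign * spec.spike.amplitude_sigma * max(spec.noise_sd, _TINY)

    gt = GroundTruth(drift=spec.drift, tr=tr, tr_metrics=tr_metrics,
                     osc_times=osc_times,
                     osc_height=spec.osc.amplitude if spec.osc else np.nan,
                     osc_fwhm=spec.osc.fwhm if spec.osc else np.nan,
                     spike_idx=spike_idx, noise_sd=spec.noise_sd,
                     osc_truncated=truncated)
    return Trace(trace_id=trace_id, times=times, values=F), gt


def standard_tr_fixture(seed: int, snr: float = 20.0, amplitude: float = 1.0,
                        with_drift: bool = True) -> FixtureSpec:
    """The stock recovery fixture: drifting baseline plus one transient.

    SNR is defined as TR amplitude over the Gaussian noise SD.
    """
    drift = DriftParams(a1=0.15 * amplitude, tau1=40.0, m1=-0.0008 * amplitude,
                        z=1.0) if with_drift else DriftParams(z=1.0)
    return FixtureSpec(drift=drift, tr=default_response(amplitude=amplitude),
                       noise_sd=amplitude / snr, seed=seed)
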