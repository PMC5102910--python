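"""Baseline drift: model, epoch delimitation, and successive least-squares fits.

The slow nuisance baseline of a fluorescence record is modeled as up to two
saturating-exponential-plus-linear components,

    d(t; a, tau, m) = a * (1 - exp(-t/tau)) + m * t,

combined semi-piecewise: the initial drift ``d1`` acts throughout, a secondary
drift ``d2`` switches on at ``t2`` (normally where the deactivation of the
transient ends), and ``z`` is the offset at t = 0.

Delimitation separates the transient-response epoch from the drift-dominated
epochs purely through order statistics of the TV derivative estimate ``u_hat``
— no amplitude threshold on the raw data is ever applied, which keeps the
procedure invariant to additive offsets and robust to drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .config import PipelineConfig
from .tv import TVState

_TINY = 1e-12


# ---------------------------------------------------------------------------
# drift model
# ---------------------------------------------------------------------------

@dataclass
class DriftParams:
    a1: float = 0.0
    tau1: float = 1.0
    m1: float = 0.0
    a2: float = 0.0
    tau2: float = 1.0
    m2: float = 0.0
    t2: float = np.inf       # secondary drift start; inf = single component
    z: float = 0.0           # offset at t = 0
    flags: list[str] = field(default_factory=list)

    def as_vector(self) -> np.ndarray:
        return np.array([self.a1, self.tau1, self.m1, self.a2, self.tau2, self.m2, self.z])

    @classmethod
    def from_vector(cls, v, t2, flags=None) -> "DriftParams":
        return cls(a1=v[0], tau1=v[1], m1=v[2], a2=v[3], tau2=v[4], m2=v[5],
                   t2=t2, z=v[6], flags=list(flags or []))


def drift_component(t, a: float, tau: float, m: float):
    """Single drift component a*(1 - exp(-t/tau)) + m*t; requires tau > 0."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    return a * (1.0 - np.exp(-t / tau)) + m * t


def drift_component_derivative(t, a: float, tau: float, m: float):
    t = np.asarray(t, dtype=float)
    return (a / tau) * np.exp(-t / tau) + m


def global_drift(t, p: DriftParams):
    """Semi-piecewise drift D(t): d1(t) + z, plus d2(t - t2) for t >= t2.

    Continuous at t2 because every component vanishes at argument 0.
    """
    t = np.asarray(t, dtype=float)
    out = drift_component(t, p.a1, p.tau1, p.m1) + p.z
    if np.isfinite(p.t2):
        late = t >= p.t2
        if np.any(late):
            out = np.where(late, out + drift_component(np.maximum(t - p.t2, 0.0),
                                                       p.a2, p.tau2, p.m2), out)
    return out


def global_drift_derivative(t, p: DriftParams):
    """Analytic dD/dt, matching :func:`global_drift` branch for branch."""
    t = np.asarray(t, dtype=float)
    out = drift_component_derivative(t, p.a1, p.tau1, p.m1)
    if np.isfinite(p.t2):
        late = t >= p.t2
        if np.any(late):
            out = np.where(late, out + drift_component_derivative(
                np.maximum(t - p.t2, 0.0), p.a2, p.tau2, p.m2), out)
    return out


# ---------------------------------------------------------------------------
# delimitation of the transient epoch
# ---------------------------------------------------------------------------

@dataclass
class Delimitation:
    i_local: np.ndarray          # significant local maxima of u_hat
    i_plus0: int = 0
    i_act0: int | None = None    # earliest activation
    i_max0: int | None = None    # selected significant derivative maximum
    i_max_end: int | None = None # where the per-sample change drops below noise
    i_max: int | None = None     # response maximum (argmax of Au on the window)
    i_end0: int | None = None    # end of deactivation
    nu_minus: np.ndarray | None = None
    mu: np.ndarray | None = None
    n_end: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def has_activation(self) -> bool:
        return self.i_local.size > 0


def _local_maxima_above(u: np.ndarray, thr: float) -> np.ndarray:
    # endpoints excluded: one-sided boundary estimates of the derivative are
    # not evidence of a maximum
    mask = (u[1:-1] > thr) & (u[1:-1] >= u[:-2]) & (u[1:-1] >= u[2:])
    return np.flatnonzero(mask) + 1


def delimit(times: np.ndarray, tvstate: TVState) -> Delimitation:
    """Locate the transient-response epoch from the TV derivative estimate.

    All index formulas operate on u_hat and its running integral Au; see the
    module docstring for the rationale of each step.
    """
    u = tvstate.u
    au = tvstate.au
    n = u.size

    u_std = u.std(ddof=1)
    if u_std <= _TINY:
        return Delimitation(i_local=np.array([], dtype=int), flags=["flat_derivative"])
    i_local = _local_maxima_above(u, u_std)
    if i_local.size == 0:
        return Delimitation(i_local=i_local, flags=["no_significant_maxima"])

    i_local0 = int(i_local.min())

    # non-negative-derivative window [i_plus0, i_local0]
    i_plus0 = 0
    for i in range(i_local0, -1, -1):
        if u[i] < 0:
            i_plus0 = i + 1
            break
    window = u[i_plus0:i_local0 + 1]
    wstd = window.std(ddof=1) if window.size > 1 else 0.0
    below = np.flatnonzero(window < wstd)
    i_act0 = i_plus0 + int(below.max()) if below.size else i_plus0

    # previous/next non-positive-derivative crossings around each maximum
    nonpos = u <= 0
    q_idx = np.empty(i_local.size, dtype=int)
    r_idx = np.empty(i_local.size, dtype=int)
    for s, r in enumerate(i_local):
        before = np.flatnonzero(nonpos[:r])
        q_idx[s] = before.max() if before.size else 0
        after = np.flatnonzero(nonpos[r + 1:])
        r_idx[s] = r + 1 + after.min() if after.size else n - 1

    # baseline extrapolation nu_minus and average activation rate mu
    dtqr = np.maximum(times[r_idx] - times[q_idx], _TINY)
    u_mid = 0.5 * (u[np.maximum(r_idx - 1, 0)] + u[r_idx])
    nu_minus = au[q_idx] + dtqr * u_mid
    mu = (au[r_idx] - nu_minus) / dtqr

    ok = (mu >= mu.mean() - 3.0 * (mu.std(ddof=1) if mu.size > 1 else 0.0)) & \
         (nu_minus >= nu_minus.mean() - (nu_minus.std(ddof=1) if nu_minus.size > 1 else 0.0))
    flags = []
    if np.any(ok):
        i_max0 = int(i_local[np.flatnonzero(ok).min()])
    else:
        i_max0 = int(i_local[0])
        flags.append("rate_filter_empty")

    # end of the significant activation: per-sample change below sigma_minus
    dts = np.concatenate([[times[1] - times[0]], np.diff(times)])
    cand = np.flatnonzero(u[i_max0:] * dts[i_max0:] < tvstate.sigma_minus)
    i_max_end = i_max0 + int(cand.min()) if cand.size else n - 1
    # the noise-level test is a proxy for the derivative's zero crossing (the
    # response maximum); at low signal-to-noise it can trip mid-rise, so the
    # search window is extended at least to the first non-positive derivative
    zero = np.flatnonzero(u[i_max0:] <= 0)
    i_zero = i_max0 + int(zero.min()) if zero.size else n - 1
    i_max_end = max(i_max_end, i_zero)

    seg = au[i_max0:i_max_end + 1]
    i_max = i_max0 + int(np.argmax(seg))

    # staircase test on |u_hat| over the decay: pick the strictest level
    # n_end that some derivative magnitude still exceeds, and declare the
    # transient negligible after the LAST such exceedance -- from there on
    # the derivative stays within its typical decay band and the (secondary)
    # drift dominates
    decay = np.abs(u[i_max:])
    d_mean = decay.mean()
    d_std = decay.std(ddof=1) if decay.size > 1 else 0.0
    n_end = 0
    for cand_n in (3, 2, 1, 0):
        if np.any(decay - d_mean > cand_n * d_std):
            n_end = cand_n
            break
    exceed = np.flatnonzero(decay - d_mean > n_end * d_std)
    if exceed.size:
        i_end0 = min(i_max + int(exceed.max()) + 1, n - 1)
    else:
        i_end0 = n - 1
        flags.append("no_decay_exceedance")

    return Delimitation(
        i_local=i_local, i_plus0=i_plus0, i_act0=i_act0, i_max0=i_max0,
        i_max_end=i_max_end, i_max=i_max, i_end0=i_end0,
        nu_minus=nu_minus, mu=mu, n_end=n_end, flags=flags,
    )


# ---------------------------------------------------------------------------
# drift fitting
# ---------------------------------------------------------------------------

def drift_index_set(n: int, delim: Delimitation, clean_mask: np.ndarray) -> np.ndarray:
    """Indices k: pre-activation plus post-deactivation, spikes removed."""
    mask = np.zeros(n, dtype=bool)
    if delim.i_act0 is not None:
        mask[: delim.i_act0 + 1] = True
    if delim.i_end0 is not None:
        mask[delim.i_end0:] = True
    if delim.i_act0 is None and delim.i_end0 is None:
        mask[:] = True
    return np.flatnonzero(mask & clean_mask)


def _fit_bounds(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    span = times[-1] - times[0]
    dt = np.median(np.diff(times))
    big = np.inf
    # tau capped at the record span: longer time constants are linearly
    # degenerate with the slope term and only add unconstrained curvature
    lo = np.array([-big, dt, -big, -big, dt, -big, -big])
    hi = np.array([big, span, big, big, span, big, big])
    return lo, hi


def amplitude_ridge_weight(n_points: int, sigma: float, range_f: float) -> float:
    """Weight of the tiny ridge on the exponential amplitudes a1, a2.

    The exponential and linear drift terms are nearly collinear over short
    windows, and inside a wide unconstrained gap the exponentials can bow the
    baseline arbitrarily while matching the fitted segments.  A ridge on
    a/range(F) with weight ~ sqrt(n)*sigma resolves that degeneracy toward
    the flattest drift at a cost far below one genuinely misfit sample.
    """
    return float(np.sqrt(max(n_points, 1)) * max(sigma, _TINY) / max(range_f, _TINY))


def fit_drift_initial(
    times: np.ndarray,
    F: np.ndarray,
    delim: Delimitation,
    clean_mask: np.ndarray,
    config: PipelineConfig | None = None,
    two_components: bool = True,
) -> DriftParams:
    """Plain least squares of the drift model over the drift-dominated points.

    Multistart over decades of tau1 guards against the exponential/linear
    degeneracy of the model; falls back to a constant baseline when too few
    usable points remain.
    """
    cfg = config or PipelineConfig()
    k = drift_index_set(F.size, delim, clean_mask)
    t2 = times[delim.i_end0] if (two_components and delim.i_end0 is not None
                                 and delim.i_end0 < F.size - 1) else np.inf
    if k.size < 8:
        pre = F[: delim.i_act0 + 1] if delim.i_act0 else F[:8]
        return DriftParams(z=float(np.median(pre)), t2=t2, flags=["too_few_drift_points"])

    tk, fk = times[k], F[k]
    span = times[-1] - times[0]
    lo, hi = _fit_bounds(times)
    sigma = 1.4826 * np.median(np.abs(np.diff(fk))) / np.sqrt(2.0) if fk.size > 2 else 0.0
    wr = amplitude_ridge_weight(k.size, sigma, np.ptp(F))

    def resid(v):
        p = DriftParams.from_vector(v, t2)
        return np.concatenate([global_drift(tk, p) - fk, [wr * v[0], wr * v[3]]])

    slope0 = (fk[-1] - fk[0]) / max(tk[-1] - tk[0], _TINY)
    best = None
    taus = np.geomspace(span / 20.0, 2.0 * span, max(cfg.drift_multistart, 1))
    for tau0 in taus:
        x0 = np.array([0.0, tau0, slope0, 0.0, tau0, 0.0, fk[0]])
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), max_nfev=200)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return DriftParams(z=float(np.median(fk)), t2=t2, flags=["drift_fit_failed"])
    return DriftParams.from_vector(best.x, t2)


def drift_weights(times, u_hat, theta0: DriftParams, k: np.ndarray) -> np.ndarray:
    """w_k = exp(-y^2 / mean(y^2)), y = |u_hat - dD/dt(t; theta0)| on k."""
    y = np.abs(u_hat[k] - global_drift_derivative(times[k], theta0))
    msq = np.mean(y ** 2)
    if msq <= _TINY:
        return np.ones(k.size)
    return np.exp(-(y ** 2) / msq)


def fit_drift_weighted(
    times: np.ndarray,
    F: np.ndarray,
    tvstate: TVState,
    delim: Delimitation,
    theta0: DriftParams,
    config: PipelineConfig | None = None,
) -> tuple[DriftParams, np.ndarray]:
    """Weighted refit combining value and derivative misfit.

    Minimizes sum_k w_k [ (D - F)^2 + (u_hat - dD/dt)^2 ] starting from the
    plain fit; the weights de-emphasize stretches whose derivative the first
    fit cannot explain (e.g. an early secondary trend before activation).
    """
    k = drift_index_set(F.size, delim, tvstate.clean_mask)
    if k.size < 8:
        return replace(theta0, flags=theta0.flags + ["weighted_refit_skipped"]), np.ones(k.size)
    w = drift_weights(times, tvstate.u, theta0, k)
    sw = np.sqrt(w)
    tk, fk, uk = times[k], F[k], tvstate.u[k]
    lo, hi = _fit_bounds(times)
    wr = amplitude_ridge_weight(k.size, tvstate.sigma_minus, np.ptp(F))

    def resid(v):
        p = DriftParams.from_vector(v, theta0.t2)
        rv = sw * (global_drift(tk, p) - fk)
        rd = sw * (global_drift_derivative(tk, p) - uk)
        return np.concatenate([rv, rd, [wr * v[0], wr * v[3]]])

    x0 = np.clip(theta0.as_vector(), lo, hi)
    try:
        sol = least_squares(resid, x0, bounds=(lo, hi), max_nfev=200)
        out = DriftParams.from_vector(sol.x, theta0.t2)
        # the weights exist to stop the trends from growing unjustifiably
        # large; if the refit nevertheless worsens the plain misfit on the
        # drift points it has chased a down-weighted subset -- keep theta0
        mse0 = np.mean((global_drift(tk, theta0) - fk) ** 2)
        mse1 = np.mean((global_drift(tk, out) - fk) ** 2)
        if mse1 > 1.5 * mse0 + _TINY:
            out = replace(theta0, flags=theta0.flags + ["weighted_refit_rejected"])
    except Exception:
        out = replace(theta0, flags=theta0.flags + ["weighted_refit_failed"])
    return out, w


def drift_objective(times, F, u_hat, p: DriftParams, k: np.ndarray,
                    w: np.ndarray | None = None) -> float:
    """S_drift value used both in refits and in the detection decision."""
    if k.size == 0:
        return 0.0
    if w is None:
        w = np.ones(k.size)
    rv = global_drift(times[k], p) - F[k]
    rd = global_drift_derivative(times[k], p) - u_hat[k]
    return float(np.sum(w * (rv ** 2 + rd ** 2)))
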