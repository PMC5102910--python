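"""Multi-peaked responses: deviation detection, reliability-weighted TR
refit, coherent-oscillation clustering, and oscillatory parameters.

Deviations are peaks and troughs of the residual between the TV data
estimate and the fitted transient baseline (truncated at its half-maximum so
an oscillation coincident with the response onset is not swallowed by the
model).  Whether the deviations form *coherent* oscillations — as opposed to
stochastic discharges — is decided in the (period, width) feature plane:
consecutive same-type events define (T, xi) pairs, a Gaussian mixture is fit
with the number of components chosen by the gap statistic, and temporally
adjacent clusters are merged when a linear period/width trend of one
predicts the neighbour's first event.  The package reports metrics for all
deviations and for the coherent subset separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_widths
from sklearn.mixture import GaussianMixture

from .config import PipelineConfig
from .drift import DriftParams, global_drift
from .transient import (ResponseParams, global_response, global_response_derivative,
                        response_model)
from .tv import TVState

_TINY = 1e-12


@dataclass
class DeviationSet:
    peak_idx: np.ndarray
    peak_times: np.ndarray
    peak_heights: np.ndarray
    peak_fwhm: np.ndarray
    trough_idx: np.ndarray
    trough_times: np.ndarray
    trough_heights: np.ndarray
    trough_fwhm: np.ndarray
    coherent_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    coherent_troughs: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    flags: list[str] = field(default_factory=list)

    @property
    def n_peak(self) -> int:
        return int(self.peak_times.size)

    @property
    def n_trough(self) -> int:
        return int(self.trough_times.size)

    @property
    def n_tilde(self) -> int:
        return self.n_peak + self.n_trough


@dataclass
class MPRMetrics:
    n_osc: int = 0
    magnitude_E: float = np.nan
    period_T: float = np.nan
    sigma_T: float = np.nan
    persistence_l_osc: float = np.nan
    duty_cycle: float = np.nan


# ---------------------------------------------------------------------------
# deviation finding
# ---------------------------------------------------------------------------

def find_deviations(
    times: np.ndarray,
    tvstate: TVState,
    response: ResponseParams | None,
    drift: DriftParams,
    config: PipelineConfig | None = None,
) -> DeviationSet:
    """Peaks/troughs of the TV estimate around the fitted baseline.

    The baseline is the global response model when a transient was fitted
    (truncated at half its amplitude above the drift) or the drift alone.
    Events shorter than ``mpr_min_height_sigma * sigma_minus`` or closer than
    ``mpr_min_spacing_s`` are not deviations.
    """
    cfg = config or PipelineConfig()
    dvals = global_drift(times, drift if response is None else response.drift)
    if response is not None:
        g = np.atleast_1d(response_model(times, response))
        amp = g.max()
        baseline = dvals + np.minimum(g, 0.5 * amp)
    else:
        baseline = dvals
    r = tvstate.au - baseline

    dt = float(np.median(np.diff(times)))
    height = cfg.mpr_min_height_sigma * max(tvstate.sigma_minus, _TINY)
    distance = max(int(np.ceil(cfg.mpr_min_spacing_s / dt)), 1)

    def _events(signal):
        idx, props = find_peaks(signal, height=height, distance=distance)
        if idx.size:
            w = peak_widths(signal, idx, rel_height=0.5)[0] * dt
        else:
            w = np.zeros(0)
        return idx, times[idx], props.get("peak_heights", np.zeros(0)), w

    pi, pt, ph, pw = _events(r)
    ti_, tt, th, tw = _events(-r)
    return DeviationSet(peak_idx=pi, peak_times=pt, peak_heights=ph, peak_fwhm=pw,
                        trough_idx=ti_, trough_times=tt, trough_heights=th,
                        trough_fwhm=tw,
                        coherent_peaks=np.zeros(pi.size, dtype=bool),
                        coherent_troughs=np.zeros(ti_.size, dtype=bool))


# ---------------------------------------------------------------------------
# reliability weighting
# ---------------------------------------------------------------------------

def bias_weights(dev: DeviationSet) -> tuple[float, float]:
    """Peak/trough bias from the relative heights of the first events.

    o_peak = exp(-(E1_peak/E1_trough)^4) and symmetrically for troughs: the
    side whose first event towers over the other is treated as deviation
    rather than baseline.  With one side absent the bias is all on the
    present side.
    """
    if dev.n_peak == 0 and dev.n_trough == 0:
        return 1.0, 1.0
    # one-sided deviation sets follow the formula's limit: as the absent
    # side's first height goes to zero, the present side's bias vanishes
    # (its deviations depart from the baseline and are unreliable) while the
    # absent side's bias saturates at one
    if dev.n_trough == 0:
        return 0.05, 1.0
    if dev.n_peak == 0:
        return 1.0, 0.05
    ratio = dev.peak_heights[0] / max(dev.trough_heights[0], _TINY)
    o_peak = float(np.exp(-min(ratio ** 4, 700.0)))
    o_trough = float(np.exp(-min(ratio ** -4, 700.0)))
    return o_peak, o_trough


def _pi_weight(t, event_times, event_fwhm, o, phi):
    """Sum over events of the printed two-branch Gaussian bump weight."""
    if event_times.size == 0 or o <= 0:
        return np.zeros_like(t)
    xi = np.maximum(event_fwhm, _TINY)
    z = phi * (o * (t[:, None] - event_times[None, :]) / xi[None, :]) ** 2
    bump = np.exp(-np.minimum(z, 700.0))
    return (o * bump + (1.0 - o) * (1.0 - bump)).sum(axis=1)


def reliability_weights(
    times: np.ndarray,
    tvstate: TVState,
    response: ResponseParams,
    dev: DeviationSet,
    o_peak: float,
    o_trough: float,
) -> np.ndarray:
    """Per-point weights Omega down-weighting oscillation-dominated epochs.

    Combines proximity to detected deviations (pi weights, scaled by the
    noise-to-signal ratio phi) with how well the local derivative matches the
    fitted response (Gamma); Omega >= 0 by subtraction of the pi minima.
    """
    phi = max(tvstate.phi, _TINY)
    pi_p = _pi_weight(times, dev.peak_times, dev.peak_fwhm, o_peak, phi)
    pi_t = _pi_weight(times, dev.trough_times, dev.trough_fwhm, o_trough, phi)
    du = tvstate.u - np.atleast_1d(global_response_derivative(times, response))
    s = du.std(ddof=1)
    gamma_w = np.exp(-((du / (2.0 * s)) ** 2)) if s > _TINY else np.ones_like(du)
    omega = gamma_w * (pi_p + pi_t - pi_p.min() - pi_t.min())
    return np.maximum(omega, 0.0)


def refit_response_weighted(
    times: np.ndarray,
    F: np.ndarray,
    tvstate: TVState,
    delim,
    act_fit,
    omega: np.ndarray,
    config: PipelineConfig | None = None,
) -> ResponseParams:
    """Omega-weighted rerun of the full response fit (baseline for MPRs)."""
    from .transient import fit_response

    return fit_response(times, F, tvstate, delim, act_fit, config=config,
                        omega=omega[tvstate.clean_idx])


# ---------------------------------------------------------------------------
# coherent-oscillation clustering
# ---------------------------------------------------------------------------

def _pair_features(dev: DeviationSet) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, int]]]:
    """(T, xi) features for consecutive same-type event pairs, time-ordered.

    Returns feature matrix, pair mid-times, and (kind, left, right) indices.
    """
    feats, mids, pairs = [], [], []
    for kind, t, w in (("peak", dev.peak_times, dev.peak_fwhm),
                       ("trough", dev.trough_times, dev.trough_fwhm)):
        for r in range(1, t.size):
            feats.append([t[r] - t[r - 1], 0.5 * (w[r] + w[r - 1])])
            mids.append(0.5 * (t[r] + t[r - 1]))
            pairs.append((kind, r - 1, r))
    if not feats:
        return np.zeros((0, 2)), np.zeros(0), []
    feats = np.asarray(feats)
    mids = np.asarray(mids)
    order = np.argsort(mids)
    return feats[order], mids[order], [pairs[i] for i in order]


def _gap_statistic_k(X: np.ndarray, k_max: int, B: int, rng: np.random.Generator) -> int:
    """Optimal component count by the gap statistic on GMM labelings."""
    def disp(data, labels, k):
        w = 0.0
        for c in range(k):
            pts = data[labels == c]
            if pts.size:
                w += ((pts - pts.mean(axis=0)) ** 2).sum()
        return max(w, _TINY)

    lo, hi = X.min(axis=0), X.max(axis=0)
    gaps, sks = [], []
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             reg_covar=1e-6, random_state=int(rng.integers(2 ** 31)))
        labels = gm.fit_predict(X)
        logw = np.log(disp(X, labels, k))
        ref = []
        for _ in range(B):
            Xr = rng.uniform(lo, hi, size=X.shape)
            gmr = GaussianMixture(n_components=k, covariance_type="full",
                                  reg_covar=1e-6, random_state=int(rng.integers(2 ** 31)))
            ref.append(np.log(disp(Xr, gmr.fit_predict(Xr), k)))
        ref = np.asarray(ref)
        gaps.append(ref.mean() - logw)
        sks.append(ref.std(ddof=1) * np.sqrt(1.0 + 1.0 / B) if B > 1 else 0.0)
    for k in range(1, k_max):
        if gaps[k - 1] >= gaps[k] - sks[k]:
            return k
    return k_max


def cluster_coherent(dev: DeviationSet, seed: int = 0,
                     config: PipelineConfig | None = None) -> DeviationSet:
    """Label the subset of deviations forming coherent oscillations.

    Clusters consecutive-event (period, width) pairs with a Gaussian mixture
    (components by gap statistic), keeps the dominant cluster, then merges
    temporally adjacent clusters whose first pair is predicted by the linear
    period/width trend of the current coherent set (within two within-cluster
    standard deviations per coordinate).  Both endpoints of every coherent
    pair are marked.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    X, mids, pairs = _pair_features(dev)
    dev.coherent_peaks = np.zeros(dev.n_peak, dtype=bool)
    dev.coherent_troughs = np.zeros(dev.n_trough, dtype=bool)
    if len(pairs) == 0:
        return dev
    if len(pairs) == 1:
        labels = np.zeros(1, dtype=int)
        coherent_pairs = np.ones(1, dtype=bool)
    else:
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        sd = np.where(sd > _TINY, sd, 1.0)
        Z = (X - mu) / sd
        k_max = max(1, min(cfg.gmm_kmax, dev.n_tilde // 2, len(pairs)))
        try:
            k = _gap_statistic_k(Z, k_max, cfg.gap_B, rng)
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 reg_covar=1e-6, random_state=int(rng.integers(2 ** 31)))
            labels = gm.fit_predict(Z)
        except Exception:
            labels = np.zeros(len(pairs), dtype=int)
            dev.flags.append("gmm_degenerate")
        # the oscillation cluster is the one that is simultaneously tight
        # and well populated: mixed pairs that straddle an interloper are
        # numerous but widely scattered in (T, xi)
        best_score, main = np.inf, 0
        for lab in np.unique(labels):
            pts = Z[labels == lab]
            if pts.shape[0] < 2 and np.unique(labels).size > 1:
                continue
            disp = ((pts - pts.mean(axis=0)) ** 2).sum(axis=1).mean()
            # dispersion floor (standardized units): below it clusters are
            # equally tight and population should decide
            score = (disp + 0.1) / pts.shape[0]
            if score < best_score:
                best_score, main = score, lab
        coherent_pairs = labels == main
        coherent_pairs = _trend_merge(X, mids, labels, coherent_pairs)

    for sel, (kind, a, b) in zip(coherent_pairs, pairs):
        if not sel:
            continue
        if kind == "peak":
            dev.coherent_peaks[[a, b]] = True
        else:
            dev.coherent_troughs[[a, b]] = True

    # rescue pass: an event whose both flanking pairs were broken by an
    # interloper can still belong to the train if the coherent trend
    # predicts it (spacing near the coherent period, width near the
    # coherent widths); progressively update the set
    _rescue_by_trend(dev.peak_times, dev.peak_fwhm, dev.coherent_peaks)
    _rescue_by_trend(dev.trough_times, dev.trough_fwhm, dev.coherent_troughs)
    return dev


def _rescue_by_trend(t, width, coherent):
    if coherent.sum() < 3:
        return
    changed = True
    while changed:
        changed = False
        ct = t[coherent]
        T_hat = np.median(np.diff(np.sort(ct))) if ct.size > 1 else 0.0
        if T_hat <= 0:
            return
        w_coh = width[coherent]
        w_tol = 2.0 * max(w_coh.std(ddof=1), 0.15 * max(w_coh.mean(), _TINY))
        for i in np.flatnonzero(~coherent):
            gap = np.abs(ct - t[i]).min()
            # nearest coherent neighbour about one period away, same width
            if abs(gap - T_hat) <= 0.3 * T_hat and abs(width[i] - w_coh.mean()) <= w_tol:
                coherent[i] = True
                changed = True


def _trend_merge(X, mids, labels, coherent):
    """Absorb neighbouring clusters consistent with the coherent trend."""
    changed = True
    while changed:
        changed = False
        in_set = np.flatnonzero(coherent)
        if in_set.size < 2:
            break
        t0, t1 = mids[in_set].min(), mids[in_set].max()
        # linear trend of each feature vs time over the coherent set
        A = np.vstack([mids[in_set], np.ones(in_set.size)]).T
        coefs = [np.linalg.lstsq(A, X[in_set, c], rcond=None)[0]
                 for c in range(X.shape[1])]
        for lab in np.unique(labels[~coherent]):
            cand = np.flatnonzero((labels == lab) & ~coherent)
            if cand.size == 0:
                continue
            # the candidate cluster's pair nearest to the coherent epoch
            before = cand[mids[cand] < t0]
            after = cand[mids[cand] > t1]
            probes = []
            if after.size:
                probes.append(after[np.argmin(mids[after])])
            if before.size:
                probes.append(before[np.argmax(mids[before])])
            if not probes:
                continue
            spread = X[cand].std(axis=0, ddof=1) if cand.size > 1 else np.zeros(X.shape[1])
            tol = 2.0 * np.maximum(spread, 0.25 * np.maximum(X[coherent].std(axis=0, ddof=1), _TINY))
            ok = False
            for p in probes:
                pred = np.array([c[0] * mids[p] + c[1] for c in coefs])
                if np.all(np.abs(X[p] - pred) <= tol):
                    ok = True
            if ok:
                coherent = coherent | (labels == lab)
                changed = True
    return coherent


# ---------------------------------------------------------------------------
# oscillatory parameters
# ---------------------------------------------------------------------------

def mpr_metrics(dev: DeviationSet, which: str = "all") -> MPRMetrics:
    """The six oscillatory parameters for all deviations or the coherent set."""
    if which == "coherent":
        pt = dev.peak_times[dev.coherent_peaks]
        ph = dev.peak_heights[dev.coherent_peaks]
        pw = dev.peak_fwhm[dev.coherent_peaks]
        th = dev.trough_heights[dev.coherent_troughs]
    else:
        pt, ph, pw = dev.peak_times, dev.peak_heights, dev.peak_fwhm
        th = dev.trough_heights

    n_osc = int(pt.size)
    mag = np.nan
    if ph.size:
        mag = float(ph.mean()) + (float(th.mean()) if th.size else 0.0)
    if pt.size >= 2:
        T = np.diff(pt)
        period = float(T.mean())
        sigma_T = float(T.std(ddof=1)) if T.size > 1 else 0.0
        l_osc = float(pt[-1] - pt[0])
        duty = float(pw.mean() / period) if period > 0 else np.nan
    else:
        period = sigma_T = l_osc = duty = np.nan
    return MPRMetrics(n_osc=n_osc, magnitude_E=mag, period_T=period,
                      sigma_T=sigma_T, persistence_l_osc=l_osc, duty_cycle=duty)
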