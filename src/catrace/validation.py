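"""Agreement statistics between two sets of paired parameter estimates.

Used to compare manual against automated estimates (or ground truth against
recovered values): per-pair Z-scores and percent differences, the 95%
Bland-Altman interval of agreement, and a correlation summary against the
line of identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class AgreementStats:
    z_scores: np.ndarray
    pct_diff: np.ndarray
    mean_pct_diff: float
    loa_low: float
    loa_high: float
    slope: float
    r2: float
    n_used: int
    flags: list[str] = field(default_factory=list)


def bland_altman(manual, auto) -> AgreementStats:
    """Percent-difference agreement analysis of paired estimates.

    For each pair, x_i = (m_i + a_i)/2, Z_i = (x_i - mean x)/std x and
    Xi_i = (a_i - m_i)/x_i * 100%; the interval of agreement is
    mean(Xi) +/- 1.96 * std(Xi).  Negative Xi means the manual estimate
    exceeds the automated one.  Pairs with x_i = 0 are excluded and flagged.
    """
    m = np.asarray(manual, dtype=float)
    a = np.asarray(auto, dtype=float)
    if m.shape != a.shape:
        raise ValueError("paired inputs must have equal length")
    finite = np.isfinite(m) & np.isfinite(a)
    x = (m + a) / 2.0
    ok = finite & (x != 0.0)
    flags = []
    if np.any(finite & ~ok):
        flags.append("zero_mean_pairs_excluded")
    if np.any(~finite):
        flags.append("nonfinite_pairs_excluded")
    m, a, x = m[ok], a[ok], x[ok]

    sx = x.std(ddof=1) if x.size > 1 else 0.0
    z = (x - x.mean()) / sx if sx > 0 else np.zeros_like(x)
    xi = (a - m) / x * 100.0
    xi_bar = float(xi.mean()) if xi.size else np.nan
    s_xi = float(xi.std(ddof=1)) if xi.size > 1 else 0.0
    slope, r2 = correlation_summary(m, a)
    return AgreementStats(z_scores=z, pct_diff=xi, mean_pct_diff=xi_bar,
                          loa_low=xi_bar - 1.96 * s_xi, loa_high=xi_bar + 1.96 * s_xi,
                          slope=slope, r2=r2, n_used=int(m.size), flags=flags)


def correlation_summary(manual, auto) -> tuple[float, float]:
    """OLS slope of automated on manual and the squared Pearson correlation."""
    m = np.asarray(manual, dtype=float)
    a = np.asarray(auto, dtype=float)
    if m.size < 2 or np.allclose(m, m[0]) or np.allclose(a, a[0]):
        return np.nan, np.nan
    res = stats.linregress(m, a)
    return float(res.slope), float(res.rvalue ** 2)
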