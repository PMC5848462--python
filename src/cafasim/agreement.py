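"""Agreement statistics for paired Pd/Pa curves: Pearson r, paired t,
Bland-Altman bias and limits of agreement.

Curves from the simulation and from the wire are paired one-to-one at n
positions uniform on their common axial interval (linear interpolation),
then compared with the three standard method-comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .hemodynamics import PullbackCurve


@dataclass(frozen=True)
class AgreementReport:
    n: int
    r: float
    p_r: float
    t: float
    p_t: float
    bias: float  # mean difference, method A - method B
    sd: float  # sample SD of the differences (n-1 denominator)
    loa_low: float
    loa_high: float
    degenerate_t: bool = False  # identical series: t defined as 0
    infinite_t: bool = False  # constant nonzero shift: unbounded t

    def to_dict(self) -> dict:
        return asdict(self)


def pair_curves(
    sim: PullbackCurve, wire: PullbackCurve, n: int = 18
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate both curves at n positions uniform on the common interval.

    Returns (z, sim_ratio, wire_ratio).
    """
    lo = max(sim.z.min(), wire.z.min())
    hi = min(sim.z.max(), wire.z.max())
    if hi <= lo:
        raise ValueError("curves share no common axial interval")
    z = np.linspace(lo, hi, n)
    # np.interp requires ascending abscissae; pull-backs run distal -> inlet
    sim_order = np.argsort(sim.z)
    wire_order = np.argsort(wire.z)
    s = np.interp(z, sim.z[sim_order], sim.ratio[sim_order])
    w = np.interp(z, wire.z[wire_order], wire.ratio[wire_order])
    return z, s, w


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t-distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool, bool]:
    """Paired t-test on d = x - y; returns (t, p, degenerate, infinite).

    Identical series give t = 0, p = 1 with the degenerate flag; a constant
    nonzero shift has zero-variance differences and sets the infinite flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            return 0.0, 1.0, True, False
        return float(np.inf) * np.sign(np.mean(d)), 0.0, False, True
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), False, False


def bland_altman(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, tuple[float, float], np.ndarray, np.ndarray]:
    """Bland-Altman: bias = mean(x - y), sample SD (n-1), LoA = bias +/- 1.96*sd.

    Also returns the (mean, difference) pairs for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    return bias, sd, loa, (x + y) / 2, d


def compare_curves(sim: PullbackCurve, wire: PullbackCurve, n: int = 18) -> AgreementReport:
    """Full agreement analysis of a simulated vs a wire-measured pull-back."""
    _, s, w = pair_curves(sim, wire, n)
    r, p_r = pearson_corr(s, w)
    t, p_t, degen, inf = paired_t(s, w)
    bias, sd, loa, _, _ = bland_altman(s, w)
    return AgreementReport(
        n=n, r=r, p_r=p_r, t=t, p_t=p_t, bias=bias, sd=sd,
        loa_low=loa[0], loa_high=loa[1], degenerate_t=degen, infinite_t=inf,
    )
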