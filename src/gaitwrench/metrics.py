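"""Agreement metrics and paired statistics for gait loading waveforms.

Covers: RMSE and the coefficient of determination R^2 between a reference
and an estimated waveform; extraction of the first peak, second peak and
stance impulse of a loading curve; the exact Wilcoxon signed-rank test;
Benjamini-Hochberg false-discovery-rate control; and the table-level
comparison of two workflows' per-cycle features.

R^2 here is the coefficient of determination about the reference mean
(1 - SS_res / SS_tot), not squared Pearson correlation, computed per cycle
and reported as mean +/- sd across cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelmax
from scipy.stats import rankdata


@dataclass
class AgreementStats:
    rmse: float
    r2: float
    mad_peak1: float = np.nan
    mad_peak2: float = np.nan
    mad_impulse: float = np.nan
    n: int = 0

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


@dataclass
class WaveformFeatures:
    """First/second peak (value and stance-% location) and stance impulse."""

    peak1: float
    peak1_pct: float
    peak2: float
    peak2_pct: float
    impulse: float  # value * s
    fallback_flag: bool = False


@dataclass
class TestResult:
    statistic: float  # Wilcoxon W+
    p: float
    q: float = np.nan
    reject: bool = False


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def agreement(reference: np.ndarray, estimate: np.ndarray) -> tuple[float, float]:
    """RMSE and coefficient of determination of an estimate vs a reference.

    ``r2 = 1 - SS_res / SS_tot`` with SS_tot about the reference mean.  A
    zero-variance reference makes R^2 undefined; NaN is returned for it.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(estimate, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("waveforms must have equal length >= 2")
    resid = a - b
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = np.nan if ss_tot == 0 else float(1.0 - np.sum(resid**2) / ss_tot)
    return rmse, r2


# ---------------------------------------------------------------------------
# waveform features
# ---------------------------------------------------------------------------

def extract_features(
    waveform: np.ndarray,
    stance_fraction: float,
    cycle_duration: float,
) -> WaveformFeatures:
    """First peak, second peak and impulse of a loading waveform.

    The waveform spans the full gait cycle on an equally spaced grid
    (conventionally 101 points).  Peaks are searched inside the stance
    window: the first in 0-50% of stance, the second in 50-100%, preferring
    local maxima; if a half-window holds no local maximum its global
    maximum is used and ``fallback_flag`` is set.  The impulse is the
    trapezoidal time integral over stance, in (value x s).
    """
    y = np.asarray(waveform, dtype=float)
    n = len(y)
    pct = np.linspace(0.0, 100.0, n)
    stance = pct <= stance_fraction * 100.0 + 1e-9
    if not stance.any():
        raise ValueError("stance window is empty")
    idx = np.flatnonzero(stance)
    stance_pct = pct[idx] / (stance_fraction * 100.0) * 100.0  # 0..100% of stance

    def _peak(window: np.ndarray) -> tuple[float, float, bool]:
        yw = y[idx[window]]
        sw = stance_pct[window]
        if len(yw) == 0:
            return np.nan, np.nan, True
        local = argrelmax(yw)[0]
        if len(local):
            j = local[np.argmax(yw[local])]
            return float(yw[j]), float(sw[j]), False
        j = int(np.argmax(yw))
        return float(yw[j]), float(sw[j]), True

    first = stance_pct <= 50.0
    p1, p1_pct, fb1 = _peak(first)
    p2, p2_pct, fb2 = _peak(~first)

    dt = cycle_duration / (n - 1)
    impulse = float(np.trapezoid(y[idx], dx=dt))
    return WaveformFeatures(
        peak1=p1, peak1_pct=p1_pct, peak2=p2, peak2_pct=p2_pct,
        impulse=impulse, fallback_flag=bool(fb1 or fb2),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

EXACT_N_MAX = 25


def _signed_ranks(diff: np.ndarray) -> tuple[np.ndarray, float]:
    """Mid-ranks of |d| after dropping zero differences, and W+."""
    d = diff[diff != 0]
    if len(d) == 0:
        raise ValueError("degenerate paired sample: all differences zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return ranks, w_plus


def _exact_wplus_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of W+ over all 2^n sign assignments.

    Mid-ranks can be half-integers; doubling makes them integers, so the
    distribution is built by integer convolution (equivalent to full
    enumeration but O(n * support)).
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    support = np.arange(total + 1) / 2.0
    return support, counts / counts.sum()


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's convention) and ties in |d|
    receive mid-ranks.  For n <= 25 the two-sided p-value is exact over all
    2^n sign assignments (p = min(1, 2 min(P(W+ <= w), P(W+ >= w)))); above
    that a normal approximation with continuity and tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    ranks, w_plus = _signed_ranks(x - y)
    n = len(ranks)
    if n <= EXACT_N_MAX:
        support, pmf = _exact_wplus_distribution(ranks)
        p_le = pmf[support <= w_plus + 1e-9].sum()
        p_ge = pmf[support >= w_plus - 1e-9].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        from scipy.stats import norm

        p = min(1.0, 2.0 * norm.sf(abs(z)))
    return TestResult(statistic=w_plus, p=float(p))


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvals: np.ndarray, q_threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(qvals, reject)``: q-values are the monotone-adjusted
    ``p * m / rank`` and a test is rejected iff its q-value is at most
    ``q_threshold`` (equivalent to the classic step-up rule).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    qsorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(qsorted, 1.0)
    return q, q <= q_threshold


# ---------------------------------------------------------------------------
# workflow comparison
# ---------------------------------------------------------------------------

def compare_workflows(
    ref_features: dict[str, list[WaveformFeatures]],
    est_features: dict[str, list[WaveformFeatures]],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Compare two workflows' per-cycle loading features.

    Inputs map a component name (e.g. ``"medial_kcf"``) to the per-cycle
    features of the reference and the estimating workflow, paired by cycle.
    For every (component x feature) cell the mean absolute difference and a
    Wilcoxon signed-rank p-value are computed; Benjamini-Hochberg adjusts
    across all cells.  Returns a long-format DataFrame with columns
    component, feature, mad, rmse, r2, statistic, p, q, reject.
    """
    if set(ref_features) != set(est_features):
        raise ValueError("component sets differ between workflows")
    rows = []
    for comp in ref_features:
        ref, est = ref_features[comp], est_features[comp]
        if len(ref) != len(est):
            raise ValueError(f"unpaired inputs for component {comp!r}")
        for feat in ("peak1", "peak2", "impulse"):
            a = np.array([getattr(f, feat) for f in ref])
            b = np.array([getattr(f, feat) for f in est])
            mad = float(np.mean(np.abs(a - b)))
            rmse, r2 = agreement(a, b)
            if np.all(a == b):
                stat, p = np.nan, 1.0  # identical: no evidence of difference
            else:
                res = wilcoxon_signed_rank(a, b)
                stat, p = res.statistic, res.p
            rows.append({
                "component": comp, "feature": feat, "mad": mad,
                "rmse": rmse, "r2": r2, "statistic": stat, "p": p,
            })
    table = pd.DataFrame(rows)
    qvals, reject = bh_fdr(table["p"].to_numpy(), q_threshold)
    table["q"] = qvals
    table["reject"] = reject
    return table
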