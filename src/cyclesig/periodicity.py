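"""Fisher's g test for periodicity, exact p-values, Storey q-values, and
pseudoperiodic-protein (PsP) calling.

For an N-point series the periodogram is evaluated at the Fourier
frequencies f_k = k/N, k = 1..m with m = floor((N-1)/2).  Fisher's g is the
largest periodogram ordinate divided by the sum of all ordinates; under
Gaussian white noise its null distribution is known exactly, giving an
exact p-value per series.  p-values are corrected across proteins with
Storey's q-value method, and a protein is called pseudoperiodic when its q
is below threshold in BOTH technical repeats and its dominant frequency is
one oscillation per cell cycle (1/16) or two (1/8) in both repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.special import gammaln

from .preprocess import PseudotimecourseSet, impute_series_mean

#: frequencies (cycles per population-series point) accepted for a PsP call
#: in the 16-population design: one or two oscillations per cell cycle
ALLOWED_FREQS = (1.0 / 16.0, 1.0 / 8.0)

DEFAULT_Q_THRESHOLD = 0.10


@dataclass
class Periodogram:
    n: int
    power: np.ndarray  # I[k], k = 1..m

    @property
    def m(self) -> int:
        return len(self.power)

    @property
    def degenerate(self) -> bool:
        return not np.any(self.power > 0)


def periodogram(series: np.ndarray) -> Periodogram:
    """Periodogram of a mean-centred series at the Fourier frequencies.

    I[k] = (1/N) |sum_t x_t exp(-2*pi*i*k*t/N)|^2 for k = 1..floor((N-1)/2).
    A constant series yields an all-zero (degenerate) periodogram.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains nonfinite values; impute first")
    n = x.size
    m = (n - 1) // 2
    if m < 1:
        raise ValueError("series too short for a periodogram")
    xc = x - x.mean()
    ft = np.fft.rfft(xc)
    power = (np.abs(ft[1 : m + 1]) ** 2) / n
    return Periodogram(n=n, power=power)


def fisher_g(pg: Periodogram) -> tuple[float, int]:
    """Fisher's g statistic and the dominant Fourier index.

    g = max_k I[k] / sum_k I[k]; ties on the maximum are broken toward the
    smallest index (longest period).
    """
    if pg.degenerate:
        raise ValueError("degenerate periodogram (constant series)")
    total = pg.power.sum()
    k_max = int(np.argmax(pg.power)) + 1  # argmax takes the first maximum
    return float(pg.power[k_max - 1] / total), k_max


def fisher_g_pvalue(g: float, m: int) -> float:
    """Exact null p-value of Fisher's g with m periodogram ordinates.

    P(G > g) = sum_{j=1}^{min(m, floor(1/g))} (-1)^(j-1) C(m,j) (1 - j*g)^(m-1)

    The alternating series is accumulated from log-magnitude terms to
    control cancellation; the result is clipped to [0, 1].
    """
    if not 0.0 < g <= 1.0:
        raise ValueError("g must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if m == 1:
        return 1.0  # single ordinate forces g = 1; (1-g)^(m-1) = 0^0 = 1
    j_max = min(m, int(np.floor(1.0 / g + 1e-12)))
    p = 0.0
    for j in range(1, j_max + 1):
        base = 1.0 - j * g
        if base <= 0.0:
            continue
        log_term = (
            gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1)
            + (m - 1) * np.log(base)
        )
        p += (-1.0) ** (j - 1) * np.exp(log_term)
    return float(min(max(p, 0.0), 1.0))


def storey_qvalues(pvals: np.ndarray, min_n_for_pi0: int = 100) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) with a cubic
    smoothing spline evaluated at the largest lambda, clipped to (0, 1].
    With fewer than ``min_n_for_pi0`` p-values the estimate is unstable and
    pi0 = 1 is used (Benjamini-Hochberg equivalence) with a warning.

    q_i = pi0 * min_{p_j >= p_i} (n * p_j / rank_j), monotone in p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("pvals must be a nonempty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    n = p.size

    if n < min_n_for_pi0:
        warnings.warn(
            f"only {n} p-values; falling back to pi0 = 1 (BH)", stacklevel=2
        )
        pi0 = 1.0
    else:
        lam = np.arange(0.05, 0.951, 0.05)
        pi0_lam = np.array([(p >= l).mean() / (1.0 - l) for l in lam])
        spline = UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(spline(lam.max()))
        pi0 = min(max(pi0, 1.0 / n), 1.0)

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * n * ranked / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def estimate_pi0(pvals: np.ndarray) -> float:
    """Smoother-based estimate of the null proportion pi0."""
    p = np.asarray(pvals, dtype=float)
    lam = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([(p >= l).mean() / (1.0 - l) for l in lam])
    spline = UnivariateSpline(lam, pi0_lam, k=3)
    return float(min(max(spline(lam.max()), 1.0 / p.size), 1.0))


def test_pseudotimecourses(pts: PseudotimecourseSet) -> pd.DataFrame:
    """Fisher's g test per protein per technical repeat.

    Returns a tidy frame with one row per protein x repeat: g, dominant
    index ``k_max``, ``freq`` = k_max/N, exact p, Storey q (computed within
    each repeat across testable proteins), and a ``testable`` flag.
    Untestable or degenerate series carry NaN statistics.
    """
    rows = []
    for ti in range(pts.n_techrep):
        g_arr = np.full(len(pts.protein_ids), np.nan)
        k_arr = np.full(len(pts.protein_ids), -1)
        p_arr = np.full(len(pts.protein_ids), np.nan)
        ok = np.zeros(len(pts.protein_ids), dtype=bool)
        for i in range(len(pts.protein_ids)):
            if not pts.testable[i, ti]:
                continue
            series = impute_series_mean(pts.series[i, ti])
            pg = periodogram(series)
            if pg.degenerate:
                continue
            g, k_max = fisher_g(pg)
            g_arr[i] = g
            k_arr[i] = k_max
            p_arr[i] = fisher_g_pvalue(g, pg.m)
            ok[i] = True
        q_arr = np.full(len(pts.protein_ids), np.nan)
        if ok.any():
            q_arr[ok] = storey_qvalues(p_arr[ok])
        n_points = pts.series.shape[2]
        for i, pid in enumerate(pts.protein_ids):
            rows.append(
                {
                    "protein_id": pid,
                    "techrep": ti + 1,
                    "testable": bool(ok[i]),
                    "g": g_arr[i],
                    "k_max": int(k_arr[i]),
                    "freq": k_arr[i] / n_points if k_arr[i] > 0 else np.nan,
                    "p": p_arr[i],
                    "q": q_arr[i],
                }
            )
    return pd.DataFrame(rows)


def call_psps(
    results: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    allowed_freqs: tuple[float, ...] = ALLOWED_FREQS,
) -> pd.DataFrame:
    """Call pseudoperiodic proteins from per-repeat test results.

    A protein is a PsP iff it is testable in both repeats, q < threshold in
    both, and its dominant frequency is in ``allowed_freqs`` in both.
    Returns one row per protein with per-repeat q/freq and ``is_psp``.
    """
    wide = results.pivot(index="protein_id", columns="techrep")
    out = pd.DataFrame(index=wide.index)
    techreps = sorted(results["techrep"].unique())
    freq_ok = pd.Series(True, index=wide.index)
    q_ok = pd.Series(True, index=wide.index)
    testable = pd.Series(True, index=wide.index)
    for t in techreps:
        out[f"q_rep{t}"] = wide[("q", t)]
        out[f"freq_rep{t}"] = wide[("freq", t)]
        out[f"p_rep{t}"] = wide[("p", t)]
        testable &= wide[("testable", t)].astype(bool)
        q_ok &= wide[("q", t)] < q_threshold
        freq_ok &= wide[("freq", t)].apply(
            lambda f: any(np.isclose(f, a) for a in allowed_freqs)
            if np.isfinite(f)
            else False
        )
    out["testable_both"] = testable
    out["is_psp"] = (testable & q_ok & freq_ok).fillna(False).astype(bool)
    return out
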