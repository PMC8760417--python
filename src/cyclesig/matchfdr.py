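"""Target/decoy estimation and filtering of the MS1 feature-match FDR.

In match-between-runs quantitation, features in a single-shot run are
assigned peptide identities by accurate-mass and retention-time matching to
a fractionated reference library.  Matches to a chemically modified decoy
run (dimethylated/isopropylated peptides, which cannot occur unmodified in
the library) are false by construction, so the match FDR can be estimated
as the decoy matched fraction divided by the target matched fraction.

False matches spread widely in retention-time difference, m/z difference
and m/z error, while true matches are tightly centered; filtering matches
to within 2.5 sigma (retention time) and 3 sigma (m/z difference and m/z
error) of the center removes most false matches at small cost in true
ones.  Sigma per dimension is estimated robustly (1.4826 x MAD) so the
false-match tail does not inflate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MATCH_COLUMNS = ("d_rt", "d_mz", "ppm_err")

DEFAULT_N_SIGMA = {"d_rt": 2.5, "d_mz": 3.0, "ppm_err": 3.0}


@dataclass
class FilterThresholds:
    """Per-dimension robust center and sigma plus the sigma multipliers."""

    center: dict[str, float]
    sigma: dict[str, float]
    n_sigma: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_N_SIGMA)
    )

    def window(self, dim: str) -> tuple[float, float]:
        half = self.n_sigma[dim] * self.sigma[dim]
        return self.center[dim] - half, self.center[dim] + half


@dataclass
class FdrReport:
    target_match_fraction: float
    decoy_match_fractions: list[float]
    fdr_estimate: float
    retention: float | None = None
    post_filter_fdr: float | None = None

    def to_dict(self) -> dict:
        return {
            "target_match_fraction": self.target_match_fraction,
            "decoy_match_fractions": self.decoy_match_fractions,
            "fdr_estimate": self.fdr_estimate,
            "retention": self.retention,
            "post_filter_fdr": self.post_filter_fdr,
        }


def _matched_fraction(table: pd.DataFrame) -> float:
    return float(table["matched"].mean())


def estimate_fdr(target: pd.DataFrame, decoys) -> FdrReport:
    """Match FDR as mean decoy matched fraction over target matched fraction.

    ``decoys`` is a single decoy table or a list (the estimate averages the
    per-decoy ratios, equivalently the ratio of the mean decoy fraction).
    """
    if isinstance(decoys, pd.DataFrame):
        decoys = [decoys]
    t_frac = _matched_fraction(target)
    if t_frac == 0:
        raise ValueError("target run has no matches; FDR undefined")
    d_fracs = [_matched_fraction(d) for d in decoys]
    fdr = float(np.mean([d / t_frac for d in d_fracs])) if d_fracs else 0.0
    return FdrReport(
        target_match_fraction=t_frac,
        decoy_match_fractions=d_fracs,
        fdr_estimate=fdr,
    )


def fit_match_sigmas(
    target: pd.DataFrame,
    n_sigma: dict[str, float] | None = None,
    min_matches: int = 100,
) -> FilterThresholds:
    """Robust per-dimension sigma from the matched target features.

    sigma = 1.4826 x median absolute deviation about the median, which is
    consistent for the Gaussian core and resistant to the broad false-match
    tail.  A zero-spread dimension is an error.
    """
    matched = target[target["matched"]]
    if len(matched) < min_matches:
        raise ValueError(
            f"need >= {min_matches} matched features to fit sigmas, "
            f"got {len(matched)}"
        )
    center, sigma = {}, {}
    for dim in MATCH_COLUMNS:
        vals = matched[dim].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        if mad == 0:
            raise ValueError(f"degenerate (zero-spread) dimension {dim!r}")
        center[dim] = med
        sigma[dim] = 1.4826 * mad
    return FilterThresholds(
        center=center, sigma=sigma, n_sigma=dict(n_sigma or DEFAULT_N_SIGMA)
    )


def filter_matches(
    table: pd.DataFrame, thresholds: FilterThresholds
) -> tuple[pd.DataFrame, float]:
    """Demote matches outside the sigma windows; report retention.

    A match survives only if it lies within the window in every dimension
    (boundaries inclusive).  Filtered-out matches become unmatched rows
    (their error values are cleared), so matched fractions remain defined
    against the same feature total.  Retention = surviving / initial
    matches.
    """
    out = table.copy()
    matched = out["matched"].to_numpy(dtype=bool)
    n_initial = int(matched.sum())
    keep = matched.copy()
    for dim in MATCH_COLUMNS:
        lo, hi = thresholds.window(dim)
        vals = out[dim].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            keep &= (vals >= lo) & (vals <= hi)
    removed = matched & ~keep
    out.loc[removed, "matched"] = False
    out.loc[removed, list(MATCH_COLUMNS)] = np.nan
    retention = float(keep.sum() / n_initial) if n_initial else np.nan
    return out, retention


def fdr_with_filtering(
    target: pd.DataFrame,
    decoys,
    n_sigma: dict[str, float] | None = None,
) -> tuple[FdrReport, FilterThresholds, pd.DataFrame, list[pd.DataFrame]]:
    """Full procedure: estimate FDR, fit thresholds, filter, re-estimate.

    Returns the combined report (pre-filter FDR, retention, post-filter
    FDR), the fitted thresholds, and the filtered target/decoy tables.
    """
    if isinstance(decoys, pd.DataFrame):
        decoys = [decoys]
    pre = estimate_fdr(target, decoys)
    thresholds = fit_match_sigmas(target, n_sigma=n_sigma)
    target_f, retention = filter_matches(target, thresholds)
    decoys_f = [filter_matches(d, thresholds)[0] for d in decoys]
    post = estimate_fdr(target_f, decoys_f)
    report = FdrReport(
        target_match_fraction=pre.target_match_fraction,
        decoy_match_fractions=pre.decoy_match_fractions,
        fdr_estimate=pre.fdr_estimate,
        retention=retention,
        post_filter_fdr=post.fdr_estimate,
    )
    return report, thresholds, target_f, decoys_f
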