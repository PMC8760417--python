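"""Intensity normalization and pseudotimecourse assembly.

Raw label-free intensities are first normalized to parts per million within
each sample (each sample's intensities are divided by the sample total and
multiplied by 1e6), removing between-sample differences in total protein
amount.  Each technical repeat is then assembled into one "pseudotimecourse"
per protein: the four biological replicates concatenated in order, each
running P1..P16, giving a 64-point ordered series that serves as a surrogate
time axis for cell-cycle progression.

Zero intensities are treated as missing throughout, following label-free
convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_RE = re.compile(r"^P(\d+)_B(\d+)_T(\d+)$")

#: minimum fraction of nonmissing points for a series to be testable
DEFAULT_COMPLETENESS = 0.95


def parse_sample_columns(columns) -> pd.DataFrame:
    """Parse ``P{pop}_B{biorep}_T{techrep}`` column names into a design table."""
    rows = []
    for c in columns:
        m = SAMPLE_RE.match(str(c))
        if not m:
            raise ValueError(f"sample column {c!r} does not match P*_B*_T*")
        rows.append((c, int(m.group(1)), int(m.group(2)), int(m.group(3))))
    design = pd.DataFrame(rows, columns=["sample", "population", "biorep", "techrep"])
    if design.duplicated(["population", "biorep", "techrep"]).any():
        dups = design[design.duplicated(["population", "biorep", "techrep"])]
        raise ValueError(f"duplicate design cells: {dups['sample'].tolist()}")
    return design.set_index("sample")


def ppm_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its nonmissing intensities sum to 1e6.

    Zeros (missing values) stay zero and do not contribute to the total.
    Raises if any sample is entirely missing.
    """
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative intensities")
    totals = values.sum(axis=0)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        raise ValueError(f"all-zero sample(s): {list(table.columns[dead])}")
    return table * (1e6 / totals)


@dataclass
class PseudotimecourseSet:
    """Per-technical-repeat ordered series for every protein.

    ``series`` has shape (n_proteins, n_techrep, n_biorep * n_populations)
    with NaN at missing points, ordered biological-replicate-major (biorep
    1: P1..P16, biorep 2: P1..P16, ...).  ``testable`` marks series meeting
    the completeness threshold.
    """

    protein_ids: pd.Index
    series: np.ndarray
    completeness: np.ndarray  # (n_proteins, n_techrep)
    testable: np.ndarray  # bool, same shape
    n_populations: int
    n_biorep: int

    @property
    def n_techrep(self) -> int:
        return self.series.shape[1]


def assemble_pseudotimecourses(
    ppm_table: pd.DataFrame,
    min_completeness: float = DEFAULT_COMPLETENESS,
) -> PseudotimecourseSet:
    """Order each technical repeat into one 64-point series per protein.

    Requires a complete crossed design (every population x biorep x techrep
    cell present exactly once).  A protein is testable in a repeat only if
    at least ``min_completeness`` of the series is nonmissing.
    """
    design = parse_sample_columns(ppm_table.columns)
    pops = sorted(design["population"].unique())
    bioreps = sorted(design["biorep"].unique())
    techreps = sorted(design["techrep"].unique())

    expected = {(p, b, t) for p in pops for b in bioreps for t in techreps}
    present = set(map(tuple, design[["population", "biorep", "techrep"]].to_numpy()))
    absent = expected - present
    if absent:
        raise ValueError(f"missing design cells: {sorted(absent)}")

    n_points = len(pops) * len(bioreps)
    n = len(ppm_table)
    series = np.full((n, len(techreps), n_points), np.nan)
    values = ppm_table.to_numpy(dtype=float)
    col_pos = {c: i for i, c in enumerate(ppm_table.columns)}
    for ti, t in enumerate(techreps):
        for bi, b in enumerate(bioreps):
            for pi, p in enumerate(pops):
                sample = design.index[
                    (design["population"] == p)
                    & (design["biorep"] == b)
                    & (design["techrep"] == t)
                ][0]
                series[:, ti, bi * len(pops) + pi] = values[:, col_pos[sample]]
    series[series == 0] = np.nan

    completeness = np.isfinite(series).mean(axis=2)
    testable = completeness >= min_completeness
    return PseudotimecourseSet(
        protein_ids=ppm_table.index,
        series=series,
        completeness=completeness,
        testable=testable,
        n_populations=len(pops),
        n_biorep=len(bioreps),
    )


def disassemble(pts: PseudotimecourseSet) -> pd.DataFrame:
    """Inverse of :func:`assemble_pseudotimecourses` (NaN back to 0)."""
    n_pops, n_bio = pts.n_populations, pts.n_biorep
    data = {}
    for ti in range(pts.n_techrep):
        for bi in range(n_bio):
            for pi in range(n_pops):
                col = f"P{pi + 1}_B{bi + 1}_T{ti + 1}"
                data[col] = np.nan_to_num(pts.series[:, ti, bi * n_pops + pi])
    return pd.DataFrame(data, index=pts.protein_ids)


def impute_series_mean(series: np.ndarray) -> np.ndarray:
    """Fill missing points of a series with the series mean.

    Mean imputation is neutral for the periodogram of the mean-centred
    series (imputed points contribute zero after centring).
    """
    out = np.array(series, dtype=float)
    mask = ~np.isfinite(out)
    if mask.all():
        raise ValueError("series is entirely missing")
    out[mask] = out[~mask].mean()
    return out
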