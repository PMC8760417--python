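"""Synthetic data generators for the cell-cycle proteomics pipeline.

Every downstream stage of the pipeline can be exercised, with known ground
truth, on data produced here: a FACS-style 16-population x 4-bioreplicate x
2-technical-repeat label-free abundance matrix with a planted fraction of
cell-cycle-periodic proteins, MS1 feature-match tables with a controlled
false-match rate for target/decoy FDR estimation, and random protein
sequences with degron motifs planted at controlled frequencies.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Five abundance-profile templates over one cell cycle (16 populations),
# qualitatively matching the recurring classes of cycling proteins: an
# interphase-high class that dips in mitosis, a G1/S peak, an S/G2 peak,
# a mid-mitotic peak (degraded at the metaphase-anaphase transition), and
# a late-mitotic peak (degraded at mitotic exit).  Each template is a
# fundamental cosine (period = 16 populations) plus a weak second harmonic
# so that the dominant Fourier frequency is always 1/16.
#   (name, peak population index 0-based, harmonic weight, harmonic phase)
PROFILE_TEMPLATES = (
    ("early_interphase", 1, 0.35, 0.0),
    ("g1s", 3, 0.20, np.pi / 3),
    ("s_g2", 6, 0.30, -np.pi / 3),
    ("mid_mitosis", 10, 0.40, 0.0),
    ("late_mitosis", 13, 0.25, np.pi / 2),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cell-cycle abundance dataset.

    Attributes
    ----------
    n_proteins : int
        Number of protein groups in the table.
    frac_periodic : float
        Fraction of proteins with a planted one-cycle-per-16-populations
        abundance oscillation.  The planted count is ``round(frac * n)``.
    n_populations, n_biorep, n_techrep : int
        Design dimensions.  The default 16 x 4 x 2 matches the FACS design
        the downstream signature stages assume.
    amplitude_range : (float, float)
        Peak-to-trough fold-change interval for periodic proteins; drawn
        uniformly per protein.  Lower bound must exceed 1.
    noise_cv : float
        Coefficient of variation of the multiplicative log-normal
        measurement noise.
    depth_cv : float
        CV of the per-sample total-intensity (depth) factor.
    missing_midpoint : float
        Abundance quantile (on log10 intensity, over the whole table) at
        which the missingness probability is 0.5.  Values below are
        increasingly censored (missing-not-at-random left censoring).
    missing_scale : float
        Logistic steepness of the censoring curve, in log10-intensity units.
    baseline_log10_mean, baseline_log10_sd : float
        Location/spread of per-protein baseline abundance (log10 scale).
    seed : int
        Seed for all randomness in the generator.
    """

    n_proteins: int = 5000
    frac_periodic: float = 0.02
    n_populations: int = 16
    n_biorep: int = 4
    n_techrep: int = 2
    amplitude_range: tuple[float, float] = (1.5, 4.0)
    noise_cv: float = 0.2
    depth_cv: float = 0.15
    missing_midpoint: float = 0.02
    missing_scale: float = 0.15
    baseline_log10_mean: float = 6.0
    baseline_log10_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_populations", "n_biorep", "n_techrep"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_periodic <= 1.0:
            raise ValueError("frac_periodic must be in [0, 1]")
        lo, hi = self.amplitude_range
        if lo <= 1.0 or hi < lo:
            raise ValueError("amplitude_range lower bound must be > 1 and <= upper")
        if self.noise_cv < 0 or self.depth_cv < 0:
            raise ValueError("coefficients of variation must be nonnegative")


def sample_name(pop: int, biorep: int, techrep: int) -> str:
    return f"P{pop}_B{biorep}_T{techrep}"


def template_profile(template_idx: int, n_populations: int = 16) -> np.ndarray:
    """Noise-free template over one cycle, rescaled to [0, 1]."""
    _, peak, h, phi = PROFILE_TEMPLATES[template_idx]
    theta = 2 * np.pi * (np.arange(n_populations) - peak) / n_populations
    s = np.cos(theta) + h * np.cos(2 * theta + phi)
    return (s - s.min()) / (s.max() - s.min())


def simulate_cell_cycle_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a raw label-free intensity table with planted periodicity.

    Returns
    -------
    table : DataFrame
        Proteins x samples raw intensities, indexed by protein id, columns
        named ``P{pop}_B{biorep}_T{techrep}``.  Zeros denote missing values
        (left-censored by the logistic missingness curve).
    truth : DataFrame
        Per-protein ground truth: ``is_periodic``, ``template_id``
        (template name or NA), ``peak_pop`` (1-based population of peak
        abundance), ``period`` (populations per cycle), ``amplitude``
        (peak/trough fold change), ``baseline_log10``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    pops = np.arange(1, cfg.n_populations + 1)

    protein_ids = np.array([f"PROT{i:05d}" for i in range(1, n + 1)])
    baseline = rng.normal(cfg.baseline_log10_mean, cfg.baseline_log10_sd, n)

    n_periodic = int(round(cfg.frac_periodic * n))
    periodic_idx = rng.choice(n, size=n_periodic, replace=False)
    is_periodic = np.zeros(n, dtype=bool)
    is_periodic[periodic_idx] = True
    template_id = np.full(n, -1)
    template_id[periodic_idx] = rng.integers(0, len(PROFILE_TEMPLATES), n_periodic)
    amplitude = np.ones(n)
    amplitude[periodic_idx] = rng.uniform(*cfg.amplitude_range, n_periodic)

    # log2 intensity per protein per population: baseline + oscillation
    log2_signal = np.zeros((n, cfg.n_populations))
    for t in range(len(PROFILE_TEMPLATES)):
        members = np.flatnonzero(template_id == t)
        if members.size == 0:
            continue
        prof = template_profile(t, cfg.n_populations)
        centred = prof - prof.mean()
        log2_signal[members] = np.log2(amplitude[members])[:, None] * centred[None, :]

    columns = []
    design = []  # (pop, biorep, techrep)
    for b in range(1, cfg.n_biorep + 1):
        for p in pops:
            for t in range(1, cfg.n_techrep + 1):
                columns.append(sample_name(p, b, t))
                design.append((p, b, t))
    n_samples = len(columns)
    pop_of_sample = np.array([d[0] - 1 for d in design])

    sigma_noise = np.sqrt(np.log1p(cfg.noise_cv**2))
    sigma_depth = np.sqrt(np.log1p(cfg.depth_cv**2))
    depth = np.exp(rng.normal(-sigma_depth**2 / 2, sigma_depth, n_samples))
    noise = np.exp(
        rng.normal(-sigma_noise**2 / 2, sigma_noise, (n, n_samples))
    )

    intensity = (
        10.0 ** baseline[:, None]
        * 2.0 ** log2_signal[:, pop_of_sample]
        * noise
        * depth[None, :]
    )

    # MNAR left censoring: logistic in log10 intensity
    log10_x = np.log10(intensity)
    mid = np.quantile(log10_x, cfg.missing_midpoint)
    p_miss = 1.0 / (1.0 + np.exp((log10_x - mid) / cfg.missing_scale))
    intensity[rng.random((n, n_samples)) < p_miss] = 0.0

    table = pd.DataFrame(intensity, index=pd.Index(protein_ids, name="protein_id"),
                         columns=columns)
    truth = pd.DataFrame(
        {
            "is_periodic": is_periodic,
            "template_id": [
                PROFILE_TEMPLATES[t][0] if t >= 0 else pd.NA for t in template_id
            ],
            "peak_pop": [
                PROFILE_TEMPLATES[t][1] + 1 if t >= 0 else pd.NA for t in template_id
            ],
            "period": np.where(is_periodic, cfg.n_populations, 0),
            "amplitude": np.where(is_periodic, amplitude, np.nan),
            "baseline_log10": baseline,
        },
        index=table.index,
    )
    return table, truth


# ---------------------------------------------------------------------------
# MS1 feature-match tables (target/decoy)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchSimConfig:
    """Parameters for a simulated feature-match (match-between-runs) run.

    True matches draw their retention-time difference (minutes), m/z
    difference (Da) and m/z error (ppm) from centred Gaussians; false
    matches draw uniformly over ``false_window`` (half-widths per
    dimension).  ``matched_fraction_*`` controls which share of a run's
    features receives any match at all; of the target run's matches, a
    fraction ``true_fraction`` is true.  Decoy runs contain false matches
    only.
    """

    n_target: int = 50_000
    n_decoy: int = 50_000
    true_fraction: float = 0.93
    matched_fraction_target: float = 0.32
    matched_fraction_decoy: float = 0.02
    rt_sigma: float = 0.10  # minutes
    mz_sigma: float = 0.001  # Da
    ppm_sigma: float = 1.0  # ppm
    false_window: tuple[float, float, float] = (0.7, 0.0065, 6.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_fraction <= 1.0:
            raise ValueError("true_fraction must be in [0, 1]")
        if min(self.rt_sigma, self.mz_sigma, self.ppm_sigma) <= 0:
            raise ValueError("error sigmas must be positive")
        for f in (self.matched_fraction_target, self.matched_fraction_decoy):
            if not 0.0 <= f <= 1.0:
                raise ValueError("matched fractions must be in [0, 1]")


def _match_errors(rng, n_true, n_false, cfg: MatchSimConfig):
    sig = np.array([cfg.rt_sigma, cfg.mz_sigma, cfg.ppm_sigma])
    win = np.asarray(cfg.false_window, dtype=float)
    true_err = rng.normal(0.0, 1.0, (n_true, 3)) * sig
    false_err = rng.uniform(-1.0, 1.0, (n_false, 3)) * win
    return true_err, false_err


def _match_table(rng, n_features, matched_fraction, true_fraction, cfg, is_decoy):
    n_matched = int(round(n_features * matched_fraction))
    n_true = int(round(n_matched * true_fraction))
    n_false = n_matched - n_true
    true_err, false_err = _match_errors(rng, n_true, n_false, cfg)
    err = np.vstack([true_err, false_err])
    is_false = np.concatenate(
        [np.zeros(n_true, dtype=bool), np.ones(n_false, dtype=bool)]
    )
    order = rng.permutation(n_matched)
    err, is_false = err[order], is_false[order]

    table = pd.DataFrame(
        {
            "matched": np.concatenate(
                [np.ones(n_matched, dtype=bool),
                 np.zeros(n_features - n_matched, dtype=bool)]
            ),
            "d_rt": np.concatenate([err[:, 0], np.full(n_features - n_matched, np.nan)]),
            "d_mz": np.concatenate([err[:, 1], np.full(n_features - n_matched, np.nan)]),
            "ppm_err": np.concatenate([err[:, 2], np.full(n_features - n_matched, np.nan)]),
            "is_decoy": is_decoy,
        }
    )
    truth = pd.Series(
        np.concatenate([is_false, np.zeros(n_features - n_matched, dtype=bool)]),
        name="is_false_match",
    )
    return table, truth


def simulate_match_tables(
    config: MatchSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate target and decoy feature-match tables with known labels.

    Returns ``(target, decoy, truth)`` where truth carries the per-record
    ``is_false_match`` flags for both runs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    target, t_truth = _match_table(
        rng, cfg.n_target, cfg.matched_fraction_target, cfg.true_fraction, cfg, False
    )
    decoy, d_truth = _match_table(
        rng, cfg.n_decoy, cfg.matched_fraction_decoy, 0.0, cfg, True
    )
    truth = pd.DataFrame(
        {
            "run": ["target"] * len(target) + ["decoy"] * len(decoy),
            "is_false_match": pd.concat([t_truth, d_truth], ignore_index=True),
        }
    )
    return target, decoy, truth


# ---------------------------------------------------------------------------
# Protein sequences with planted short linear motifs
# ---------------------------------------------------------------------------

def _pattern_instance(pattern: str, rng) -> str:
    """Draw one concrete amino-acid string matching a restricted pattern.

    Supports literals, ``.`` wildcards and ``[...]`` classes — the subset
    used by degron motif definitions.
    """
    out = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == ".":
            out.append(rng.choice(list(AMINO_ACIDS)))
            i += 1
        elif c == "[":
            j = pattern.index("]", i)
            out.append(rng.choice(list(pattern[i + 1 : j])))
            i = j + 1
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _pattern_regex(pattern: str) -> re.Pattern:
    # '.' must match amino acids only, not arbitrary characters
    return re.compile(pattern.replace(".", f"[{AMINO_ACIDS}]"))


def _min_match_length(pattern: str) -> int:
    return len(re.sub(r"\[[^\]]*\]", "X", pattern))


def simulate_proteome_fasta(
    n_seqs: int,
    motif_freqs: dict[str, str | float] | None = None,
    motif_patterns: dict[str, str] | None = None,
    length_range: tuple[int, int] = (100, 600),
    seed: int = 0,
    max_rerolls: int = 200,
) -> tuple[list, pd.DataFrame]:
    """Random protein sequences with motifs planted at given frequencies.

    Parameters
    ----------
    motif_freqs : dict motif-name -> planting probability.
    motif_patterns : dict motif-name -> pattern (required for every motif
        in ``motif_freqs``; see :mod:`cyclesig.motifs` for defaults).
    length_range : inclusive residue-length interval.

    Each sequence independently receives each motif with its stated
    probability, inserted at a random position.  Background residues are
    uniform over the 20 amino acids; chance occurrences of any *listed*
    motif in the background are re-rolled so the ground-truth labels are
    exact.  Returns Biopython ``SeqRecord`` objects plus a truth table of
    planted flags and positions.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    motif_freqs = dict(motif_freqs or {})
    motif_patterns = dict(motif_patterns or {})
    for name, f in motif_freqs.items():
        if not 0.0 <= float(f) <= 1.0:
            raise ValueError(f"motif frequency for {name} must be in [0, 1]")
        if name not in motif_patterns:
            raise ValueError(f"no pattern given for motif {name}")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    for name in motif_freqs:
        if _min_match_length(motif_patterns[name]) > lo:
            raise ValueError(
                f"motif {name} is longer than the minimum sequence length"
            )

    rng = np.random.default_rng(seed)
    regexes = {m: _pattern_regex(motif_patterns[m]) for m in motif_freqs}
    records, rows = [], []
    for i in range(n_seqs):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(AMINO_ACIDS), length))
        # remove chance background occurrences of listed motifs
        for _ in range(max_rerolls):
            s = "".join(seq)
            hit = None
            for rx in regexes.values():
                m = rx.search(s)
                if m:
                    hit = m
                    break
            if hit is None:
                break
            for j in range(*hit.span()):
                seq[j] = rng.choice(list(AMINO_ACIDS))
        row = {"seq_id": f"SYN{i:05d}"}
        for name, f in motif_freqs.items():
            planted = bool(rng.random() < float(f))
            pos = -1
            if planted:
                inst = _pattern_instance(motif_patterns[name], rng)
                pos = int(rng.integers(0, length - len(inst) + 1))
                seq[pos : pos + len(inst)] = list(inst)
            row[f"{name}_planted"] = planted
            row[f"{name}_pos"] = pos
        rows.append(row)
        records.append(
            SeqRecord(Seq("".join(seq)), id=row["seq_id"], description="synthetic")
        )
    truth = pd.DataFrame(rows).set_index("seq_id")
    return records, truth
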