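"""Short-linear-motif (SLiM) scanning and per-cluster enrichment tests.

Scans protein sequences for APC/C-recognition degrons — the KEN box, the
D-box (RxxL) and the ABBA motif — or any user-supplied position-restricted
pattern, and tests each cluster for motif enrichment against a background
set with a one-sided exact hypergeometric (Fisher) test.

Patterns use a restricted regular-expression syntax over the 20 amino
acids: literals, ``.`` (any residue) and ``[...]`` classes.  The ``.``
wildcard matches amino acids only; sequences containing other characters
produce a warning and those positions never match.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .simulate import AMINO_ACIDS, _pattern_regex

#: canonical degron motif patterns (ABBA per the consensus literature
#: definition; no disorder filtering is applied, so hits are sequence-only)
DEFAULT_MOTIFS: dict[str, str] = {
    "KEN": "KEN",
    "DBOX": "R..L",
    "ABBA": "F.[ILV][FHY].[DE]",
}

DEFAULT_ALPHA = 0.01

_VALID = set(AMINO_ACIDS)


def scan_sequence(seq: str, pattern: str) -> list[int]:
    """0-based start positions of all (overlapping) motif occurrences."""
    rx = _pattern_regex(pattern)
    # overlapping matches via lookahead
    look = re.compile(f"(?=({rx.pattern}))")
    return [m.start() for m in look.finditer(seq)]


def scan_motifs(
    records, motif_defs: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, dict[str, list[int]]]]:
    """Scan sequences for each motif.

    Parameters
    ----------
    records : iterable of Bio.SeqRecord (or (id, sequence) pairs).
    motif_defs : name -> pattern; defaults to the APC/C degrons.

    Returns
    -------
    hits : DataFrame indexed by sequence id, one boolean column per motif
        (>= 1 occurrence).
    positions : per sequence per motif, list of 0-based occurrence starts.
    """
    motif_defs = dict(motif_defs or DEFAULT_MOTIFS)
    rows, positions = [], {}
    warned = False
    for rec in records:
        if hasattr(rec, "seq"):
            sid, seq = rec.id, str(rec.seq).upper()
        else:
            sid, seq = rec[0], str(rec[1]).upper()
        if not warned and any(c not in _VALID for c in seq):
            warnings.warn(
                f"sequence {sid} contains non-amino-acid characters; "
                "they are treated as non-matching",
                stacklevel=2,
            )
            warned = True
        row = {"seq_id": sid}
        positions[sid] = {}
        for name, pattern in motif_defs.items():
            pos = scan_sequence(seq, pattern)
            row[name] = len(pos) > 0
            positions[sid][name] = pos
        rows.append(row)
    hits = pd.DataFrame(rows).set_index("seq_id")
    return hits, positions


def enrichment_test(
    hits: pd.DataFrame,
    cluster_membership: pd.Series,
    background_ids=None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """One-sided exact enrichment of each motif in each cluster.

    For a cluster of size n with a hits and a background of size N with A
    hits, p = P(X >= a) for X ~ Hypergeometric(N, A, n).  Fold enrichment
    is (a/n)/(A/N).  Background defaults to all scanned proteins; clusters
    must be subsets of the background.
    """
    if background_ids is None:
        background_ids = hits.index
    background_ids = pd.Index(background_ids)
    missing = background_ids.difference(hits.index)
    if len(missing):
        raise ValueError(f"background ids missing from scan: {list(missing)[:5]}")
    if len(cluster_membership) == 0:
        raise ValueError("empty cluster membership")
    if not set(cluster_membership.index) <= set(background_ids):
        raise ValueError("cluster members must be a subset of the background")

    bg = hits.loc[background_ids]
    n_bg = len(bg)
    rows = []
    for cluster, members in cluster_membership.groupby(cluster_membership):
        ids = members.index
        if len(ids) == 0:
            raise ValueError(f"cluster {cluster} is empty")
        for motif in hits.columns:
            a = int(bg.loc[ids, motif].sum())
            n = len(ids)
            big_a = int(bg[motif].sum())
            freq = a / n
            bg_freq = big_a / n_bg
            fold = freq / bg_freq if bg_freq > 0 else np.inf if a else np.nan
            p = float(hypergeom.sf(a - 1, n_bg, big_a, n))
            rows.append(
                {
                    "cluster": cluster,
                    "motif": motif,
                    "hits_in_cluster": a,
                    "cluster_size": n,
                    "hits_in_background": big_a,
                    "background_size": n_bg,
                    "frequency": freq,
                    "background_frequency": bg_freq,
                    "fold_enrichment": fold,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def multi_slim_summary(
    hits: pd.DataFrame, cluster_membership: pd.Series
) -> tuple[pd.Series, pd.DataFrame]:
    """Count distinct motif types per protein and tally multi-SLiM proteins.

    Returns the per-protein count of distinct motifs present, and a
    per-cluster table of proteins carrying >= 1, >= 2 and exactly 3 motif
    types (proteins carrying several APC/C degrons are candidate
    high-affinity substrates or pseudosubstrate inhibitors).
    """
    n_motifs = hits.sum(axis=1).astype(int)
    n_motifs.name = "n_slim_types"
    rows = []
    for cluster, members in cluster_membership.groupby(cluster_membership):
        counts = n_motifs.reindex(members.index).fillna(0).astype(int)
        rows.append(
            {
                "cluster": cluster,
                "cluster_size": len(members),
                "n_with_any": int((counts >= 1).sum()),
                "n_with_2plus": int((counts >= 2).sum()),
                "n_with_3": int((counts == 3).sum()),
            }
        )
    return n_motifs, pd.DataFrame(rows)
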