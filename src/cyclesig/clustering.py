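"""Ward clustering of pseudoperiodic-protein abundance profiles.

PsP intensities are averaged across all replicate series into a single
16-point mean profile per protein, z-standardized, and clustered by Ward's
minimum-variance agglomeration (Euclidean distances, the ward.D2
convention).  The cluster count is inspected with the elbow method
(within-cluster sum of squares versus k) and clusters are relabeled
1..k by the temporal position of their peak abundance, replacing manual
dendrogram leaf swapping with a reproducible rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .preprocess import parse_sample_columns


def mean_profiles(ppm_table: pd.DataFrame, protein_ids) -> pd.DataFrame:
    """Mean 16-point profile per protein plus its z-scaled version.

    For each population, intensities are averaged over all replicate
    samples with nonmissing (nonzero) values.  Proteins with a population
    entirely missing, or with a constant (degenerate) profile, are dropped
    with a warning.  Returns a frame with columns ``mean_P1..mean_P16`` and
    ``scaled_P1..scaled_P16`` (mean 0, sd 1 with n-1 denominator).
    """
    sub = ppm_table.loc[list(protein_ids)].replace(0.0, np.nan)
    design = parse_sample_columns(sub.columns)
    pops = sorted(design["population"].unique())
    means = pd.DataFrame(index=sub.index)
    for p in pops:
        cols = design.index[design["population"] == p]
        means[f"mean_P{p}"] = sub[cols].mean(axis=1)

    incomplete = means.isna().any(axis=1)
    values = means.to_numpy()
    sd = np.nanstd(values, axis=1, ddof=1)
    degenerate = pd.Series(sd == 0, index=means.index) & ~incomplete
    drop = incomplete | degenerate
    if drop.any():
        warnings.warn(
            f"dropping {int(drop.sum())} protein(s) with incomplete or "
            f"constant mean profiles: {list(means.index[drop])[:10]}",
            stacklevel=2,
        )
        means = means[~drop]

    arr = means.to_numpy()
    scaled = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(
        axis=1, ddof=1, keepdims=True
    )
    for i, p in enumerate(pops):
        means[f"scaled_P{p}"] = scaled[:, i]
    return means


def scaled_matrix(profiles: pd.DataFrame) -> np.ndarray:
    cols = [c for c in profiles.columns if c.startswith("scaled_")]
    return profiles[cols].to_numpy()


@dataclass
class ClusterModel:
    k: int
    labels: pd.Series  # protein_id -> 1..k
    linkage_matrix: np.ndarray

    def members(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]


def ward_cluster(profiles: pd.DataFrame, k: int) -> ClusterModel:
    """Agglomerative Ward clustering of the scaled profiles, cut at k."""
    X = scaled_matrix(profiles)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(X):
        raise ValueError(f"k={k} exceeds number of profiles ({len(X)})")
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=profiles.index, name="cluster")
    return ClusterModel(k=k, labels=labels, linkage_matrix=Z)


def within_cluster_ss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        members = X[labels == lab]
        total += float(((members - members.mean(axis=0)) ** 2).sum())
    return total


def elbow_wss(
    profiles: pd.DataFrame, k_range: range = range(2, 11)
) -> tuple[pd.Series, int]:
    """Within-cluster sum of squares per k from the Ward cut.

    Returns the WSS curve and the max-curvature k (largest second
    difference of the curve; requires at least three k values, else the
    smallest k is returned).
    """
    X = scaled_matrix(profiles)
    ks = [k for k in k_range if k <= len(X)]
    Z = linkage(X, method="ward")
    wss = {}
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust")
        wss[k] = within_cluster_ss(X, labels)
    curve = pd.Series(wss, name="wss")
    if len(ks) >= 3:
        second_diff = curve.to_numpy()[:-2] - 2 * curve.to_numpy()[1:-1] + curve.to_numpy()[2:]
        elbow_k = int(curve.index[1 + int(np.argmax(second_diff))])
    else:
        elbow_k = int(curve.index[0])
    return curve, elbow_k


def order_clusters_by_peak(
    model: ClusterModel, profiles: pd.DataFrame
) -> ClusterModel:
    """Relabel clusters 1..k by ascending peak position of the cluster mean.

    The peak is the argmax population of the cluster-mean scaled profile;
    ties go to the lower population index.  The membership partition is
    unchanged — only labels are permuted.
    """
    X = scaled_matrix(profiles)
    labels = model.labels.to_numpy()
    peaks = {}
    for lab in np.unique(labels):
        mean_prof = X[labels == lab].mean(axis=0)
        peaks[lab] = int(np.argmax(mean_prof))  # argmax: first index on ties
    order = sorted(peaks, key=lambda lab: (peaks[lab], lab))
    remap = {old: new + 1 for new, old in enumerate(order)}
    new_labels = pd.Series(
        [remap[l] for l in labels], index=model.labels.index, name="cluster"
    )
    return ClusterModel(k=model.k, labels=new_labels, linkage_matrix=model.linkage_matrix)
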