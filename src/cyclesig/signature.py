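"""Cell-cycle-state (CCS) signature: PCA wheel, k-NN population
classification, aggregation of 16 populations into 8 CCSs, and Spearman
assignment of query proteomes.

The signature is the set of pseudoperiodic proteins (PsPs).  Their
per-protein z-scaled abundances over the 128 samples place the 16 FACS
populations on a cyclic trajectory ("cell cycle wheel") in the first two
principal components.  The 16 population mean profiles are aggregated into
8 CCSs by k-means; an external query proteome (log-ratios, missing values
allowed) is assigned the CCS whose signature profile it rank-correlates
with best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata, spearmanr
from sklearn.cluster import KMeans

from .preprocess import parse_sample_columns

DEFAULT_N_CCS = 8
DEFAULT_KNN_K = 6
DEFAULT_MIN_OVERLAP = 30


# ---------------------------------------------------------------------------
# Signature construction
# ---------------------------------------------------------------------------

@dataclass
class SignatureModel:
    """PsP-based cell-cycle signature.

    ``sample_matrix``: samples x PsPs, each protein z-scaled across samples.
    ``pop_means``: 16 populations x PsPs (mean of scaled values).
    ``pop_to_ccs``: population (1..16) -> CCS label (1..n_ccs), surjective.
    ``ccs_profiles``: CCS x PsPs, mean of member populations' profiles.
    """

    psp_ids: list
    sample_matrix: pd.DataFrame
    sample_design: pd.DataFrame
    pop_means: pd.DataFrame
    pop_to_ccs: dict = field(default_factory=dict)
    ccs_profiles: pd.DataFrame | None = None


def build_signature(ppm_table: pd.DataFrame, psp_ids) -> SignatureModel:
    """Assemble the scaled sample matrix and population means for the PsPs.

    Zeros are treated as missing; each protein is z-scaled across all
    samples (n-1 denominator) and residual missing entries are set to 0
    (the protein's scaled mean), keeping downstream PCA/k-NN well-defined.
    """
    psp_ids = [p for p in psp_ids if p in ppm_table.index]
    if not psp_ids:
        raise ValueError("no signature proteins present in the table")
    sub = ppm_table.loc[psp_ids].replace(0.0, np.nan)
    arr = sub.to_numpy(dtype=float)
    mu = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant signature protein(s)",
            stacklevel=2,
        )
    scaled = (arr[keep] - mu[keep]) / sd[keep]
    scaled = np.nan_to_num(scaled, nan=0.0)
    kept_ids = [p for p, k in zip(psp_ids, keep) if k]

    sample_matrix = pd.DataFrame(
        scaled.T, index=sub.columns, columns=kept_ids
    )
    design = parse_sample_columns(sub.columns)
    pop_means = sample_matrix.groupby(design["population"].to_numpy()).mean()
    pop_means.index.name = "population"
    return SignatureModel(
        psp_ids=kept_ids,
        sample_matrix=sample_matrix,
        sample_design=design,
        pop_means=pop_means,
    )


# ---------------------------------------------------------------------------
# PCA wheel
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    var_explained: np.ndarray  # percentages, sums to 100


def pca_wheel(
    sample_matrix: pd.DataFrame, interphase_samples=None
) -> PcaResult:
    """Centered SVD-based PCA of the scaled sample matrix.

    Constant features are dropped with a warning.  PCA components are
    sign-ambiguous; the sign of PC1 is fixed to be positive on the mean of
    ``interphase_samples`` (all samples if not given).
    """
    X = sample_matrix.to_numpy(dtype=float)
    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant feature(s)", stacklevel=2)
        X = X[:, ~const]
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u * s
    var = s**2
    var_explained = 100.0 * var / var.sum()

    ref = (
        sample_matrix.index.isin(interphase_samples)
        if interphase_samples is not None
        else np.ones(len(sample_matrix), dtype=bool)
    )
    if scores[ref, 0].mean() < 0:
        scores[:, 0] *= -1
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=sample_matrix.index, columns=cols),
        var_explained=var_explained,
    )


def circular_rank_correlation(angles: np.ndarray, order: np.ndarray) -> float:
    """Circular-circular rank correlation between observed angles and a
    known cyclic order (1..n), insensitive to rotation and direction.

    Both variables are mapped to uniform ranks on the circle and the
    Fisher-Lee circular correlation is returned as an absolute value
    (the wheel's rotation direction is arbitrary).
    """
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    a = 2 * np.pi * rankdata(angles) / n
    b = 2 * np.pi * rankdata(order) / n

    # U-statistic form (no circular mean needed for uniform ranks):
    # correlation of pairwise angle differences
    i, j = np.triu_indices(n, k=1)
    num = np.sum(np.sin(a[i] - a[j]) * np.sin(b[i] - b[j]))
    den = np.sqrt(
        np.sum(np.sin(a[i] - a[j]) ** 2) * np.sum(np.sin(b[i] - b[j]) ** 2)
    )
    return float(abs(num / den))


# ---------------------------------------------------------------------------
# k-NN population classification
# ---------------------------------------------------------------------------

def knn_classify(
    train_matrix: np.ndarray,
    train_labels,
    test_matrix: np.ndarray,
    k: int = DEFAULT_KNN_K,
) -> np.ndarray:
    """Euclidean k-NN majority vote.

    Ties on the vote are broken toward the label with the smallest mean
    neighbor distance, then toward the lowest label.
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    test_matrix = np.asarray(test_matrix, dtype=float)
    train_labels = np.asarray(train_labels)
    if train_matrix.shape[1] != test_matrix.shape[1]:
        raise ValueError("train and test feature dimensions differ")
    if len(train_matrix) < k:
        raise ValueError(f"need at least k={k} training samples")
    d = cdist(test_matrix, train_matrix)
    out = []
    for row in d:
        nn = np.argsort(row, kind="mergesort")[:k]
        labs, counts = np.unique(train_labels[nn], return_counts=True)
        top = labs[counts == counts.max()]
        if len(top) == 1:
            out.append(top[0])
            continue
        mean_dist = {
            lab: row[nn[train_labels[nn] == lab]].mean() for lab in top
        }
        best = sorted(top, key=lambda lab: (mean_dist[lab], lab))[0]
        out.append(best)
    return np.array(out)


def leave_one_biorep_out(
    model: SignatureModel, test_biorep: int, k: int = DEFAULT_KNN_K
) -> tuple[np.ndarray, np.ndarray]:
    """Population prediction for one held-out biological replicate.

    Both technical repeats of the remaining bioreps form the training set.
    Returns (true populations, predicted populations) for the test samples.
    """
    design = model.sample_design
    test_mask = (design["biorep"] == test_biorep).to_numpy()
    X = model.sample_matrix.to_numpy()
    y = design["population"].to_numpy()
    pred = knn_classify(X[~test_mask], y[~test_mask], X[test_mask], k=k)
    return y[test_mask], pred


# ---------------------------------------------------------------------------
# CCS aggregation and Spearman assignment
# ---------------------------------------------------------------------------

def aggregate_ccs(
    model: SignatureModel, n_ccs: int = DEFAULT_N_CCS, seed: int = 0,
    n_restarts: int = 100,
) -> SignatureModel:
    """k-means aggregation of the 16 population profiles into n_ccs CCSs.

    Best inertia over ``n_restarts`` random initializations with a fixed
    seed.  CCS labels are renumbered by circular temporal order of member
    populations, anchored so that the cluster containing P1 is CCS1.
    Profiles are the means of member population profiles.
    """
    pops = model.pop_means.index.to_numpy()
    X = model.pop_means.to_numpy()
    if len(pops) < n_ccs:
        raise ValueError("fewer populations than requested CCSs")
    km = KMeans(n_clusters=n_ccs, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)

    # temporal order: sort clusters by their earliest member population
    first_pop = {lab: pops[raw == lab].min() for lab in np.unique(raw)}
    order = sorted(first_pop, key=lambda lab: first_pop[lab])
    remap = {old: new + 1 for new, old in enumerate(order)}
    pop_to_ccs = {int(p): remap[lab] for p, lab in zip(pops, raw)}

    profiles = {}
    for ccs in sorted(set(pop_to_ccs.values())):
        members = [p for p, c in pop_to_ccs.items() if c == ccs]
        profiles[f"CCS{ccs}"] = model.pop_means.loc[members].mean(axis=0)
    ccs_profiles = pd.DataFrame(profiles).T
    ccs_profiles.index.name = "ccs"
    model.pop_to_ccs = pop_to_ccs
    model.ccs_profiles = ccs_profiles
    return model


@dataclass
class CcsAssignment:
    experiment_id: str
    rho: pd.Series  # per CCS
    n_overlap: int
    best_ccs: str | None
    p: float
    assigned: bool = False
    reason: str = ""


def spearman_assign(
    query: pd.Series,
    model: SignatureModel,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    experiment_id: str = "query",
) -> CcsAssignment:
    """Assign a query proteome to the best-correlated CCS.

    ``query`` maps protein ids to (normalized) values, NaN allowed.  For
    each CCS, Spearman's rho is computed over the signature proteins with
    values present in both the query and the profile.  The best CCS is the
    argmax rho; its p-value comes from the large-sample t approximation.
    Queries overlapping fewer than ``min_overlap`` signature proteins are
    left unassigned.  Batch-level multiple-testing control is applied by
    :func:`assign_batch`.
    """
    if model.ccs_profiles is None:
        raise ValueError("model has no CCS profiles; run aggregate_ccs first")
    common = [p for p in model.psp_ids if p in query.index]
    vals = query.reindex(common).astype(float)
    present = vals.notna()
    n_overlap = int(present.sum())
    if n_overlap < min_overlap:
        return CcsAssignment(
            experiment_id, pd.Series(dtype=float), n_overlap, None, np.nan,
            False, f"overlap {n_overlap} < {min_overlap}",
        )
    rho = {}
    for ccs in model.ccs_profiles.index:
        prof = model.ccs_profiles.loc[ccs].reindex(common)
        mask = present & prof.notna()
        r, _ = spearmanr(vals[mask], prof[mask])
        rho[ccs] = float(r)
    rho = pd.Series(rho)
    best = rho.idxmax()
    r = rho[best]
    # t approximation at n_overlap points
    df = n_overlap - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2)) if abs(r) < 1 else np.inf
    from scipy.stats import t as t_dist

    p = float(t_dist.sf(t, df))  # one-sided: positive correlation
    return CcsAssignment(experiment_id, rho, n_overlap, str(best), p)


def assign_batch(
    queries: dict[str, pd.Series],
    model: SignatureModel,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, list[CcsAssignment]]:
    """Assign a batch of query proteomes with Benjamini-Hochberg control.

    Returns a report frame (one row per experiment: rho per CCS, best CCS,
    overlap, raw and BH-adjusted p, assigned flag) and the assignment
    objects.
    """
    assignments = [
        spearman_assign(q, model, min_overlap=min_overlap, experiment_id=eid)
        for eid, q in queries.items()
    ]
    testable = [a for a in assignments if a.best_ccs is not None]
    if testable:
        pvals = np.array([a.p for a in testable])
        order = np.argsort(pvals, kind="mergesort")
        n = len(pvals)
        adj = np.empty(n)
        ranked = pvals[order] * n / np.arange(1, n + 1)
        adj[order] = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
        for idx, a in enumerate(testable):
            a.assigned = bool(adj[idx] < fdr)
            a.reason = f"BH-adjusted p = {adj[idx]:.3g}"
    rows = []
    for a in assignments:
        row = {"experiment_id": a.experiment_id, "n_overlap": a.n_overlap,
               "best_ccs": a.best_ccs, "p": a.p, "assigned": a.assigned,
               "note": a.reason}
        for ccs, r in a.rho.items():
            row[f"rho_{ccs}"] = r
        rows.append(row)
    return pd.DataFrame(rows), assignments


def normalize_query(
    raw: pd.DataFrame | pd.Series,
    mode: str = "silac_log_ratio",
    value_col: str | None = None,
    reference_col: str | None = None,
) -> pd.Series:
    """Normalize a query proteome to centered log-ratios.

    ``silac_log_ratio``: values are already log-ratios; center to median 0.
    ``lfq_vs_reference``: compute log2(sample / reference) from intensity
    columns, nonpositive ratios become missing, then center.
    """
    if mode == "silac_log_ratio":
        vals = raw if isinstance(raw, pd.Series) else raw[value_col or raw.columns[0]]
        vals = vals.astype(float)
    elif mode == "lfq_vs_reference":
        if isinstance(raw, pd.Series) or reference_col is None:
            raise ValueError("lfq_vs_reference needs a frame with a reference column")
        sample = raw[value_col or raw.columns[0]].astype(float)
        ref = raw[reference_col].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = sample / ref
        ratio[(sample <= 0) | (ref <= 0)] = np.nan
        vals = np.log2(ratio)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return vals - vals.median()
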