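"""End-to-end pipeline: simulate/ingest -> normalize -> periodicity ->
PsP calling -> clustering -> motif enrichment -> CCS signature."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clustering, io, motifs, periodicity, preprocess, signature
from .simulate import SimConfig, simulate_cell_cycle_dataset

log = logging.getLogger("cyclesig")


@dataclass
class PipelineConfig:
    """All pipeline thresholds and paths; serialized with every run."""

    output_dir: str = "cyclesig_run"
    abundance_tsv: str | None = None  # if None, simulate
    fasta: str | None = None
    dialect: str = "synthetic"
    sim: SimConfig = field(default_factory=SimConfig)
    q_threshold: float = periodicity.DEFAULT_Q_THRESHOLD
    min_completeness: float = preprocess.DEFAULT_COMPLETENESS
    n_clusters: int = 5
    knn_k: int = signature.DEFAULT_KNN_K
    n_ccs: int = signature.DEFAULT_N_CCS
    min_overlap: int = signature.DEFAULT_MIN_OVERLAP
    enrichment_alpha: float = motifs.DEFAULT_ALPHA
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**data.pop("sim", {}))
        return cls(sim=sim, **data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Independent per-stage substreams from one master seed."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts plus a run manifest.

    Returns the manifest dict.  Any stage failure aborts with the stage
    name in the exception message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}

    def _write(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        artifacts[name] = _sha256(path)

    stage = "input"
    try:
        if config.abundance_tsv:
            table = io.read_abundance_tsv(config.abundance_tsv, dialect=config.dialect)
            truth = None
        else:
            sim_cfg = SimConfig(**{**asdict(config.sim), "seed": seeds[0]})
            table, truth = simulate_cell_cycle_dataset(sim_cfg)
            _write(table, "abundance.tsv", index_label="protein_id")
            _write(truth, "ground_truth.tsv", index_label="protein_id")
        counts["proteins"] = len(table)
        counts["samples"] = table.shape[1]

        stage = "normalize"
        ppm = preprocess.ppm_normalize(table)
        _write(ppm, "abundance_ppm.tsv", index_label="protein_id")

        stage = "pseudotimecourses"
        pts = preprocess.assemble_pseudotimecourses(
            ppm, min_completeness=config.min_completeness
        )
        counts["testable_both_repeats"] = int(pts.testable.all(axis=1).sum())

        stage = "periodicity"
        results = periodicity.test_pseudotimecourses(pts)
        _write(results, "periodicity.tsv", index=False)
        calls = periodicity.call_psps(results, q_threshold=config.q_threshold)
        _write(calls, "psp_calls.tsv", index_label="protein_id")
        psp_ids = list(calls.index[calls["is_psp"]])
        counts["psps"] = len(psp_ids)
        log.info("periodicity: %d PsPs of %d tested", len(psp_ids),
                 counts["testable_both_repeats"])

        stage = "clustering"
        cluster_labels = None
        if len(psp_ids) >= config.n_clusters:
            profiles = clustering.mean_profiles(ppm, psp_ids)
            wss, elbow_k = clustering.elbow_wss(profiles)
            _write(wss.to_frame(), "elbow_wss.tsv", index_label="k")
            model = clustering.ward_cluster(profiles, config.n_clusters)
            model = clustering.order_clusters_by_peak(model, profiles)
            cluster_labels = model.labels
            _write(
                profiles.assign(cluster=model.labels), "psp_clusters.tsv",
                index_label="protein_id",
            )
            counts["elbow_k"] = elbow_k
        else:
            log.warning("clustering skipped: only %d PsPs", len(psp_ids))

        stage = "motif_enrichment"
        if config.fasta and cluster_labels is not None:
            records = io.read_fasta(config.fasta)
            hits, _ = motifs.scan_motifs(records)
            background = hits.index.intersection(calls.index[calls["testable_both"]])
            members = cluster_labels[cluster_labels.index.isin(background)]
            enr = motifs.enrichment_test(
                hits, members, background_ids=background,
                alpha=config.enrichment_alpha,
            )
            _write(enr, "slim_enrichment.tsv", index=False)
            _, multi = motifs.multi_slim_summary(hits, members)
            _write(multi, "multi_slim.tsv", index=False)
        elif config.fasta is None:
            log.info("no FASTA given: motif enrichment skipped")

        stage = "signature"
        sig = None
        if len(psp_ids) >= 3:
            sig = signature.build_signature(ppm, psp_ids)
            interphase = sig.sample_design.index[
                sig.sample_design["population"] <= sig.sample_design["population"].max() // 2
            ]
            pca = signature.pca_wheel(sig.sample_matrix, interphase_samples=interphase)
            _write(pca.scores.iloc[:, :4], "pca_scores.tsv", index_label="sample")
            counts["pc1_var_pct"] = round(float(pca.var_explained[0]), 1)
            counts["pc2_var_pct"] = round(float(pca.var_explained[1]), 1)
            sig = signature.aggregate_ccs(sig, n_ccs=config.n_ccs, seed=seeds[1])
            io.save_signature_model(sig, out / "signature_model")
            for name in ("sample_matrix.tsv", "pop_means.tsv", "ccs_profiles.tsv",
                         "model.json"):
                artifacts[f"signature_model/{name}"] = _sha256(
                    out / "signature_model" / name
                )
        else:
            log.warning("signature skipped: only %d PsPs", len(psp_ids))
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "counts": counts,
        "artifacts": artifacts,
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
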