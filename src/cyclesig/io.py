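"""Readers and writers for the pipeline's tabular dialects.

Two abundance-table dialects are supported: the native synthetic TSV
(first column ``protein_id``, remaining columns named ``P{pop}_B{bio}_T{tech}``)
and a MaxQuant proteinGroups-style TSV where intensity columns carry a
configurable prefix (``Intensity P3_B2_T1`` -> sample ``P3_B2_T1``).
Feature-match tables and query proteomes are plain TSV; sequences are FASTA
via Biopython.  All joins key on protein ids, so duplicate ids are errors.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .matchfdr import MATCH_COLUMNS


def _check_unique_index(df: pd.DataFrame, what: str) -> None:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


def read_abundance_tsv(
    path,
    dialect: str = "synthetic",
    id_column: str = "protein_id",
    intensity_prefix: str = "Intensity ",
) -> pd.DataFrame:
    """Read an abundance table in the synthetic or protein-groups dialect.

    ``synthetic``: every non-id column is a sample named P*_B*_T*.
    ``protein_groups``: sample columns start with ``intensity_prefix``; the
    prefix is stripped and all other columns are dropped.
    """
    df = pd.read_csv(path, sep="\t")
    if id_column not in df.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    df = df.set_index(id_column)
    if dialect == "synthetic":
        pass
    elif dialect == "protein_groups":
        cols = [c for c in df.columns if c.startswith(intensity_prefix)]
        if not cols:
            raise ValueError(
                f"no columns with prefix {intensity_prefix!r} in {path}"
            )
        df = df[cols]
        df.columns = [c[len(intensity_prefix):] for c in cols]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_unique_index(df, "protein")
    return df.astype(float)


def write_abundance_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="protein_id")


def read_match_table(path, maxquant: bool = False) -> pd.DataFrame:
    """Read a feature-match TSV.

    Native columns: matched, d_rt, d_mz, ppm_err, is_decoy.  With
    ``maxquant=True``, evidence-style columns are mapped instead
    ("Match time difference", "Match m/z difference", "Uncalibrated mass
    error [ppm]"); rows with a match time difference are flagged matched.
    """
    df = pd.read_csv(path, sep="\t")
    if maxquant:
        mapping = {
            "Match time difference": "d_rt",
            "Match m/z difference": "d_mz",
            "Uncalibrated mass error [ppm]": "ppm_err",
        }
        missing = [c for c in mapping if c not in df.columns]
        if missing:
            raise ValueError(f"missing MaxQuant columns: {missing}")
        df = df.rename(columns=mapping)
        if "matched" not in df.columns:
            df["matched"] = df["d_rt"].notna()
        if "is_decoy" not in df.columns:
            df["is_decoy"] = False
    required = {"matched", *MATCH_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"match table missing columns: {sorted(missing)}")
    return df


def write_match_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> list:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_query_tsv(path, id_column: str = "protein_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index(id_column)
    _check_unique_index(df, "protein")
    return df


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")


def save_signature_model(model, directory) -> None:
    """Serialize a SignatureModel to a TSV + JSON bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model.sample_matrix.to_csv(directory / "sample_matrix.tsv", sep="\t")
    model.pop_means.to_csv(directory / "pop_means.tsv", sep="\t")
    if model.ccs_profiles is not None:
        model.ccs_profiles.to_csv(directory / "ccs_profiles.tsv", sep="\t")
    write_json(
        {
            "psp_ids": list(model.psp_ids),
            "pop_to_ccs": {str(k): v for k, v in model.pop_to_ccs.items()},
        },
        directory / "model.json",
    )


def load_signature_model(directory):
    from .signature import SignatureModel
    from .preprocess import parse_sample_columns

    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    sample_matrix = pd.read_csv(directory / "sample_matrix.tsv", sep="\t", index_col=0)
    pop_means = pd.read_csv(directory / "pop_means.tsv", sep="\t", index_col=0)
    ccs_path = directory / "ccs_profiles.tsv"
    ccs_profiles = (
        pd.read_csv(ccs_path, sep="\t", index_col=0) if ccs_path.exists() else None
    )
    return SignatureModel(
        psp_ids=meta["psp_ids"],
        sample_matrix=sample_matrix,
        sample_design=parse_sample_columns(sample_matrix.index),
        pop_means=pop_means,
        pop_to_ccs={int(k): v for k, v in meta["pop_to_ccs"].items()},
        ccs_profiles=ccs_profiles,
    )
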