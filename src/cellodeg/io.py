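"""Readers and writers for the pipeline's tab-separated and sparse formats."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .barcodes import BarcodeProfile
from .cazymes import CAZymeProfile, parse_annotation
from .programs import UMIMatrix

__all__ = [
    "read_abundance_tsv", "write_abundance_tsv",
    "read_barcode_profiles_tsv", "write_barcode_profiles_tsv",
    "read_annotation_tsv", "write_cazyme_profiles_tsv",
    "read_umi_dir", "write_umi_dir",
    "read_gene_sets_yaml",
    "read_assay_tsv", "write_assay_tsv",
]


def read_abundance_tsv(path) -> pd.DataFrame:
    """Samples-as-rows relative-abundance TSV (first column = sample id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_abundance_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample")


def read_barcode_profiles_tsv(path) -> list[BarcodeProfile]:
    """Long-format (barcode, species, reads) TSV into per-barcode profiles."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "species": str})
    profiles = []
    for bc, grp in df.groupby("barcode", sort=True):
        profiles.append(BarcodeProfile(
            str(bc), dict(zip(grp["species"], grp["reads"].astype(int)))))
    return profiles


def write_barcode_profiles_tsv(profiles: Iterable[BarcodeProfile], path) -> None:
    rows = [
        {"barcode": p.barcode, "species": s, "reads": r}
        for p in profiles for s, r in sorted(p.species_reads.items())
    ]
    pd.DataFrame(rows, columns=["barcode", "species", "reads"]).to_csv(
        path, sep="\t", index=False)


def read_annotation_tsv(path) -> list[CAZymeProfile]:
    """Annotation TSV (genome_id, gene_id, family[, evalue, coverage])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "gene_id", "family"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation TSV must have columns {sorted(required)}")
    rows = df[["genome_id", "gene_id", "family"]].itertuples(index=False)
    return parse_annotation([tuple(r) for r in rows])


def write_cazyme_profiles_tsv(profiles: Iterable[CAZymeProfile], path) -> None:
    rows = [
        {"genome_id": p.genome_id, "family": f, "copies": c}
        for p in profiles for f, c in sorted(p.family_counts.items())
    ]
    pd.DataFrame(rows, columns=["genome_id", "family", "copies"]).to_csv(
        path, sep="\t", index=False)


def write_umi_dir(matrix: UMIMatrix, out_dir) -> None:
    """MatrixMarket triplet: matrix.mtx + barcodes.tsv + features.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(matrix.counts))
    bc = pd.DataFrame({"barcode": matrix.cell_ids})
    if matrix.sample_ids is not None:
        bc["sample_id"] = matrix.sample_ids
    if matrix.clusters is not None:
        bc["cluster"] = matrix.clusters
    bc.to_csv(out / "barcodes.tsv", sep="\t", index=False)
    pd.DataFrame({"feature_id": matrix.feature_ids}).to_csv(
        out / "features.tsv", sep="\t", index=False)


def read_umi_dir(in_dir) -> UMIMatrix:
    path = Path(in_dir)
    counts = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
    bc = pd.read_csv(path / "barcodes.tsv", sep="\t", dtype=str)
    feats = pd.read_csv(path / "features.tsv", sep="\t", dtype=str)
    return UMIMatrix(
        counts=counts,
        cell_ids=bc["barcode"].tolist(),
        feature_ids=feats["feature_id"].tolist(),
        sample_ids=bc["sample_id"].tolist() if "sample_id" in bc else None,
        clusters=bc["cluster"].to_numpy() if "cluster" in bc else None,
    )


def read_gene_sets_yaml(path) -> dict[str, list[str]]:
    """YAML of named gene sets: {set_name: [gene symbols]}."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError("gene-set YAML must map set names to symbol lists")
    return {str(k): [str(g) for g in v] for k, v in data.items()}


def read_assay_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_assay_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
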