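"""Readers and writers for the pipeline's file formats.

Formats: GMT for gene sets; TSV (gene id column + sample-id header) or
MatrixMarket with row/column sidecars for counts; CSV for phenotypes and
score tables; JSON for the synthetic-cohort truth record.  All text is
UTF-8 with '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    ScoreTable,
    ValidationError,
)

__all__ = [
    "read_gmt", "write_gmt",
    "read_counts", "write_counts_tsv", "write_counts_mtx",
    "read_phenotypes", "write_phenotypes",
    "read_scores", "write_scores",
    "write_truth", "write_cohort",
]

PHENOTYPE_CATEGORICALS = ("age_group", "race_ethnicity", "education",
                          "bmi_class", "batch")


class ParseError(ValueError):
    """A file does not conform to its format."""


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (set name, description, tab-separated members)."""
    sets: dict[str, GeneSet] = {}
    role_by_name = {"CSP": "CSP", "SIP": "SIP", "SRP": "SRP",
                    "Summary": "summary", "SenMayo": "SenMayo"}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected name, description and at "
                    f"least one member, got {len(parts)} field(s)")
            name, _desc, *members = parts
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            if len(set(members)) != len(members):
                dup = sorted({m for m in members if members.count(m) > 1})
                raise ParseError(
                    f"{path}:{lineno}: duplicate member(s) in set {name!r}: {dup[:5]}")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name=name, members=tuple(members),
                                 role=role_by_name.get(name, "custom"))
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.role, *gs.members]) + "\n")


def read_counts(path, format: str = "tsv") -> CountMatrix:
    """Read a gene x sample count matrix from TSV or MatrixMarket.

    The MTX format expects ``<stem>.genes.txt`` and ``<stem>.samples.txt``
    sidecars next to the matrix file (one id per line).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text(encoding="utf-8").split()
        samples = Path(f"{stem}.samples.txt").read_text(encoding="utf-8").split()
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        df = pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"),
                          columns=samples)
    else:
        raise ParseError(f"unknown counts format {format!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError(f"{path}: counts must be numeric")
    try:
        return CountMatrix(values=df)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_counts_tsv(counts: CountMatrix, path) -> None:
    df = counts.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_counts_mtx(counts: CountMatrix, path) -> None:
    """MatrixMarket (1-based coordinates) plus gene/sample id sidecars."""
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.values.to_numpy()))
    stem = path.with_suffix("")
    Path(f"{stem}.genes.txt").write_text(
        "\n".join(map(str, counts.gene_ids)) + "\n", encoding="utf-8")
    Path(f"{stem}.samples.txt").write_text(
        "\n".join(map(str, counts.sample_ids)) + "\n", encoding="utf-8")


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate a phenotype CSV (sample_id index).

    Missing cells stay missing (complete-case handling happens per model in
    the association stage); structural violations (nonpositive weights,
    unknown vital-status codes, out-of-range multimorbidity or cognition)
    are rejected.
    """
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    if "weight" in df.columns:
        w = df["weight"].dropna()
        if (w <= 0).any():
            bad = df.index[df["weight"] <= 0].tolist()
            raise ParseError(f"{path}: nonpositive survey weight for {bad[:5]}")
    if "vital_status" in df.columns:
        vs = df["vital_status"].dropna()
        if not set(np.asarray(vs, dtype=float)) <= {1.0, 2.0, 3.0, 4.0}:
            bad = sorted(set(np.asarray(vs, dtype=float)) - {1.0, 2.0, 3.0, 4.0})
            raise ParseError(f"{path}: unknown vital-status code(s) {bad}")
    if "multimorbidity" in df.columns:
        mm = df["multimorbidity"].dropna()
        if ((mm < 0) | (mm > 5)).any() or not np.allclose(mm, np.round(mm)):
            raise ParseError(f"{path}: multimorbidity must be an integer in [0, 5]")
    if "cognition" in df.columns:
        cg = df["cognition"].dropna()
        if ((cg < 0) | (cg > 27)).any():
            raise ParseError(f"{path}: cognition must lie in [0, 27]")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index_label="sample_id")


def read_scores(path) -> ScoreTable:
    df = pd.read_csv(path, index_col=0)
    return ScoreTable(values=df, g_used={})


def write_scores(scores: ScoreTable, path) -> None:
    scores.values.to_csv(path, index_label="sample_id")


def write_truth(truth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def write_cohort(cohort, outdir, mtx: bool = False) -> dict[str, str]:
    """Write all components of a synthetic cohort; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_counts_tsv(cohort.counts, outdir / "counts.tsv")
    paths["counts"] = str(outdir / "counts.tsv")
    if mtx:
        write_counts_mtx(cohort.counts, outdir / "counts.mtx")
        paths["counts_mtx"] = str(outdir / "counts.mtx")
    write_phenotypes(cohort.phenotypes, outdir / "phenotypes.csv")
    paths["phenotypes"] = str(outdir / "phenotypes.csv")
    write_gmt(cohort.gene_sets, outdir / "gene_sets.gmt")
    paths["gene_sets"] = str(outdir / "gene_sets.gmt")
    write_truth(cohort.truth, outdir / "truth.json")
    paths["truth"] = str(outdir / "truth.json")
    return paths
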