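"""Readers and writers for the standard on-disk formats.

Conversions between file conventions and the internal 1-based closed
coordinate system happen here and nowhere else:

* BED is 0-based, half-open -> internal start = Start+1, end = End.
* GFF3 is 1-based, closed -> passed through unchanged.
* Score matrices are TSV (header row = marker ids, first column = gene ids)
  or MatrixMarket coordinate format with two sidecar id files; sparse input
  is densified with explicit zeros at load time.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import pyranges as pr
import scipy.io
import scipy.sparse

from .model import (GeneAnnotation, GeneSetCollection, GenomeDescription,
                    MarkerMap, ParseError, ScoreMatrix,
                    TissueExpressionMatrix)

_FLOAT_FMT = "%.17g"     # round-trips float64 exactly


# ---------------------------------------------------------------- score matrix

def _mtx_sidecars(path: str) -> tuple[str, str]:
    stem = os.path.splitext(path)[0]
    return stem + ".genes.txt", stem + ".markers.txt"


def read_score_matrix(path: str, fmt: str = "tsv") -> ScoreMatrix:
    """Load a genes x markers score matrix.

    TSV dialect: first row marker ids, first column gene ids, tab-separated
    floats; missing cells are an error (no NA support). MTX: MatrixMarket
    coordinate file plus ``<stem>.genes.txt`` / ``<stem>.markers.txt``
    sidecar id lists, one id per line.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique()
            raise ParseError(f"duplicate gene id: {', '.join(map(str, dup[:5]))}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique()
            raise ParseError(f"duplicate marker id: {', '.join(map(str, dup[:5]))}")
        try:
            values = df.astype(float)
        except ValueError as exc:
            raise ParseError(f"non-numeric cell in {path}: {exc}") from None
        if values.isna().any().any():
            rows = values.index[values.isna().any(axis=1)]
            raise ParseError(f"missing cell(s) in rows: {', '.join(rows[:5])}")
        return ScoreMatrix.from_frame(values)
    if fmt == "mtx":
        genes_path, markers_path = _mtx_sidecars(path)
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = [ln.strip() for ln in open(genes_path) if ln.strip()]
        markers = [ln.strip() for ln in open(markers_path) if ln.strip()]
        return ScoreMatrix(genes, markers, np.asarray(mat, dtype=float))
    raise ValueError(f"unknown score matrix format {fmt!r}")


def write_score_matrix(sm: ScoreMatrix, path: str, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        sm.to_frame().to_csv(path, sep="\t", index_label="gene_id",
                             float_format=_FLOAT_FMT)
    elif fmt == "mtx":
        genes_path, markers_path = _mtx_sidecars(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(sm.scores))
        with open(genes_path, "w") as fh:
            fh.write("\n".join(sm.gene_ids) + "\n")
        with open(markers_path, "w") as fh:
            fh.write("\n".join(sm.marker_ids) + "\n")
    else:
        raise ValueError(f"unknown score matrix format {fmt!r}")


# ----------------------------------------------------------------- marker map

def read_marker_map(path: str) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    return MarkerMap(df)


def write_marker_map(mm: MarkerMap, path: str) -> None:
    df = mm.df.copy()
    if df["cm"].isna().all():
        df = df.drop(columns=["cm"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ------------------------------------------------------------ gene annotation

def read_gene_annotation(path: str, fmt: str = "bed") -> GeneAnnotation:
    """Read gene locations from BED6 (0-based half-open) or GFF3 (1-based
    closed), normalising to internal 1-based closed coordinates."""
    if fmt == "bed":
        ranges = pr.read_bed(path).df
        if "Name" not in ranges.columns:
            raise ParseError("BED input needs a name column (BED4+)")
        df = pd.DataFrame({
            "gene_id": ranges["Name"],
            "chrom": ranges["Chromosome"].astype(str),
            "start_bp": ranges["Start"].astype(np.int64) + 1,
            "end_bp": ranges["End"].astype(np.int64),
            "strand": ranges["Strand"].astype(str) if "Strand" in ranges else ".",
        })
    elif fmt == "gff3":
        ranges = pr.read_gff3(path).df
        id_col = "ID" if "ID" in ranges.columns else "gene_id"
        if id_col not in ranges.columns:
            raise ParseError("GFF3 input needs ID= or gene_id= attributes")
        df = pd.DataFrame({
            "gene_id": ranges[id_col],
            # pyranges converts GFF3 to 0-based half-open on read
            "chrom": ranges["Chromosome"].astype(str),
            "start_bp": ranges["Start"].astype(np.int64) + 1,
            "end_bp": ranges["End"].astype(np.int64),
            "strand": ranges["Strand"].astype(str) if "Strand" in ranges else ".",
        })
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    df["strand"] = df["strand"].replace({"?": "."})
    return GeneAnnotation(df)


def write_gene_annotation(ga: GeneAnnotation, path: str, fmt: str = "bed") -> None:
    df = ga.df
    base = pd.DataFrame({
        "Chromosome": df["chrom"],
        "Start": df["start_bp"] - 1,
        "End": df["end_bp"],
        "Strand": df["strand"],
    })
    if fmt == "bed":
        base["Name"] = df["gene_id"].to_numpy()
        base["Score"] = 0
        pr.PyRanges(base).to_bed(path)
    elif fmt == "gff3":
        base["ID"] = df["gene_id"].to_numpy()
        base["Feature"] = "gene"
        pr.PyRanges(base).to_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")


# ------------------------------------------------------------------ gene sets

def read_gene_sets(path: str) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated
    ``set_id<TAB>description<TAB>member1<TAB>member2...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                raise ParseError(f"{path}:{lineno}: empty GMT line")
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs id, description and "
                    f"at least one member")
            sid, desc, *members = fields
            members = [m for m in members if m]
            if sid in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set id {sid!r}")
            sets[sid] = members
            descriptions[sid] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(gsc: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for sid in sorted(gsc.sets):
            desc = gsc.descriptions.get(sid, "na")
            members = "\t".join(sorted(gsc.sets[sid]))
            fh.write(f"{sid}\t{desc}\t{members}\n")


# --------------------------------------------------------------------- genome

def read_genome(path: str) -> GenomeDescription:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "length_bp"} <= set(df.columns):
        raise ParseError("genome description needs columns chrom, length_bp")
    return GenomeDescription.from_pairs(zip(df["chrom"], df["length_bp"]))


def write_genome(genome: GenomeDescription, path: str) -> None:
    pd.DataFrame({
        "chrom": list(genome.chroms),
        "length_bp": [genome.lengths[c] for c in genome.chroms],
    }).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- tissue expression

def read_tissue_matrix(path: str) -> TissueExpressionMatrix:
    """Read a genes x tissues TSV whose first line is a comment naming the
    CNS subset: ``#cns_tissues: t1,t2,...``."""
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#cns_tissues:"):
        raise ParseError("tissue matrix must start with a '#cns_tissues:' line")
    cns = [t.strip() for t in first.split(":", 1)[1].split(",") if t.strip()]
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None, skiprows=1)
    return TissueExpressionMatrix(list(df.index), list(df.columns),
                                  df.to_numpy(dtype=float), cns)


def write_tissue_matrix(tm: TissueExpressionMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#cns_tissues: " + ",".join(tm.cns_tissues) + "\n")
        tm.to_frame().to_csv(fh, sep="\t", index_label="gene_id",
                             float_format=_FLOAT_FMT)
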