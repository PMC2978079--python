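"""Core domain types for paired low-/high-resolution eQTL analysis.

All genomic coordinates held by these types are 1-based, closed intervals.
Format-specific conventions (BED half-open 0-based, GFF3 closed 1-based)
are converted at the I/O boundary only (see :mod:`qtlbridge.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A file or in-memory table violates the expected format or an invariant."""


VALID_STRANDS = {"+", "-", "."}


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Series(list(ids))
    dup = s[s.duplicated()].unique()
    if len(dup):
        raise ParseError(f"duplicate {what}: {', '.join(map(str, dup[:5]))}")


class MarkerMap:
    """Ordered genetic-marker coordinates.

    Each marker has an id, a chromosome, a physical position in bp and
    optionally a genetic position in cM. Within a chromosome the cM values
    (where present) must be non-decreasing with physical position.
    """

    def __init__(self, df: pd.DataFrame):
        required = ["marker_id", "chrom", "pos_bp"]
        for col in required:
            if col not in df.columns:
                raise ParseError(f"marker map missing column {col!r}")
        df = df.copy()
        if "cm" not in df.columns:
            df["cm"] = np.nan
        df["marker_id"] = df["marker_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        df["cm"] = df["cm"].astype(float)
        _check_unique(df["marker_id"], "marker id")
        if (df["pos_bp"] < 0).any():
            raise ParseError("marker positions must be >= 0")
        if (df["cm"].dropna() < 0).any():
            raise ParseError("cM values must be >= 0")
        df = df.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            cm = sub["cm"].dropna()
            if len(cm) >= 2 and (np.diff(cm.to_numpy()) < -1e-9).any():
                raise ParseError(f"cM not non-decreasing with position on {chrom}")
        self._df = df[["marker_id", "chrom", "pos_bp", "cm"]]
        self._row = {m: i for i, m in enumerate(df["marker_id"])}

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "MarkerMap":
        rows = list(records)
        cols = ["marker_id", "chrom", "pos_bp", "cm"][: len(rows[0]) if rows else 4]
        return cls(pd.DataFrame(rows, columns=cols))

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._row

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self._df["chrom"]))

    def markers_on(self, chrom: str) -> pd.DataFrame:
        return self._df[self._df["chrom"] == chrom]

    def position(self, marker_id: str) -> tuple[str, int]:
        try:
            row = self._df.iloc[self._row[marker_id]]
        except KeyError:
            raise KeyError(f"unknown marker {marker_id!r}") from None
        return row["chrom"], int(row["pos_bp"])

    def cm_of(self, marker_id: str) -> float:
        return float(self._df.iloc[self._row[marker_id]]["cm"])

    def ids(self) -> np.ndarray:
        return self._df["marker_id"].to_numpy()


class ScoreMatrix:
    """Dense genes x markers matrix of nonnegative association scores.

    Scores are unitless (e.g. LOD, or -log10 p). Missing values are not
    supported: sparse inputs must be densified with explicit zeros because
    quantile thresholds are defined over the full matrix.
    """

    def __init__(self, gene_ids: Sequence[str], marker_ids: Sequence[str],
                 scores: np.ndarray):
        gene_ids = np.asarray([str(g) for g in gene_ids], dtype=object)
        marker_ids = np.asarray([str(m) for m in marker_ids], dtype=object)
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2 or scores.shape != (len(gene_ids), len(marker_ids)):
            raise ParseError(
                f"score matrix shape {scores.shape} does not match "
                f"{len(gene_ids)} genes x {len(marker_ids)} markers")
        _check_unique(gene_ids, "gene id")
        _check_unique(marker_ids, "marker id")
        if not np.isfinite(scores).all():
            raise ParseError("scores must be finite")
        if (scores < 0).any():
            raise ParseError("scores must be nonnegative")
        self.gene_ids = gene_ids
        self.marker_ids = marker_ids
        self.scores = scores
        self._gidx = {g: i for i, g in enumerate(gene_ids)}
        self._midx = {m: j for j, m in enumerate(marker_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def gene_index(self, gene_id: str) -> int:
        return self._gidx[gene_id]

    def marker_index(self, marker_id: str) -> int:
        return self._midx[marker_id]

    def marker_indices(self, marker_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._midx[m] for m in marker_ids], dtype=np.intp)

    def row(self, gene_id: str) -> np.ndarray:
        return self.scores[self._gidx[gene_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.gene_ids,
                            columns=self.marker_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoreMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


class GeneAnnotation:
    """Gene (or probeset) genomic locations, 1-based closed coordinates.

    Strand is stored for completeness but ignored by all positional logic:
    search regions around genes extend symmetrically up- and downstream.
    """

    def __init__(self, df: pd.DataFrame):
        for col in ["gene_id", "chrom", "start_bp", "end_bp"]:
            if col not in df.columns:
                raise ParseError(f"gene annotation missing column {col!r}")
        df = df.copy()
        if "strand" not in df.columns:
            df["strand"] = "."
        df["gene_id"] = df["gene_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["start_bp"] = df["start_bp"].astype(np.int64)
        df["end_bp"] = df["end_bp"].astype(np.int64)
        df["strand"] = df["strand"].astype(str).replace({"unknown": "."})
        _check_unique(df["gene_id"], "gene id")
        bad = df[df["end_bp"] <= df["start_bp"]]
        if len(bad):
            raise ParseError(
                f"gene end <= start for {', '.join(bad['gene_id'].head(5))}")
        bad_strand = set(df["strand"]) - VALID_STRANDS
        if bad_strand:
            raise ParseError(f"unknown strand characters: {sorted(bad_strand)}")
        df = df.sort_values(["chrom", "start_bp"], kind="stable").reset_index(drop=True)
        self._df = df[["gene_id", "chrom", "start_bp", "end_bp", "strand"]]
        self._row = {g: i for i, g in enumerate(df["gene_id"])}

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "GeneAnnotation":
        rows = list(records)
        cols = ["gene_id", "chrom", "start_bp", "end_bp", "strand"][: len(rows[0]) if rows else 5]
        return cls(pd.DataFrame(rows, columns=cols))

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._row

    def loc(self, gene_id: str) -> pd.Series:
        try:
            return self._df.iloc[self._row[gene_id]]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def midpoint(self, gene_id: str) -> float:
        row = self.loc(gene_id)
        return 0.5 * (row["start_bp"] + row["end_bp"])

    def genes_on(self, chrom: str) -> pd.DataFrame:
        return self._df[self._df["chrom"] == chrom]

    def ids(self) -> np.ndarray:
        return self._df["gene_id"].to_numpy()

    def validate_against(self, genome: "GenomeDescription") -> None:
        """Check coordinates fall inside the described chromosomes."""
        for _, row in self._df.iterrows():
            if row["chrom"] not in genome.lengths:
                raise ParseError(f"gene {row['gene_id']} on unknown chromosome "
                                 f"{row['chrom']}")
            if row["end_bp"] > genome.lengths[row["chrom"]] or row["start_bp"] < 1:
                raise ParseError(f"gene {row['gene_id']} outside chromosome bounds")


class GeneSetCollection:
    """Mapping of set id -> nonempty set of gene ids (e.g. KEGG pathways).

    Membership of a gene in the gene annotation is not required: annotation
    coverage is reported downstream, not enforced here.
    """

    def __init__(self, sets: Mapping[str, Iterable[str]],
                 descriptions: Mapping[str, str] | None = None):
        self.sets: dict[str, frozenset[str]] = {}
        for sid, members in sets.items():
            fs = frozenset(str(m) for m in members)
            if not fs:
                raise ParseError(f"gene set {sid!r} is empty")
            self.sets[str(sid)] = fs
        self.descriptions = dict(descriptions or {})
        self._by_gene: dict[str, set[str]] = {}
        for sid, members in self.sets.items():
            for g in members:
                self._by_gene.setdefault(g, set()).add(sid)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def sets_of(self, gene_id: str) -> set[str]:
        return self._by_gene.get(gene_id, set())

    def annotated(self, gene_id: str) -> bool:
        return gene_id in self._by_gene

    def share_set(self, gene_a: str, gene_b: str) -> bool:
        """True if the two genes are co-members of at least one set.

        A gene trivially shares a set with itself provided it is annotated
        at all (the cis case: causal and target gene are identical).
        """
        if gene_a == gene_b:
            return self.annotated(gene_a)
        return bool(self.sets_of(gene_a) & self.sets_of(gene_b))


@dataclass(frozen=True)
class GenomeDescription:
    """Ordered chromosome names and lengths (bp)."""

    chroms: tuple[str, ...]
    lengths: Mapping[str, int]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeDescription":
        pairs = [(str(c), int(n)) for c, n in pairs]
        names = [c for c, _ in pairs]
        _check_unique(names, "chromosome name")
        if any(n <= 0 for _, n in pairs):
            raise ParseError("chromosome lengths must be positive")
        return cls(tuple(names), dict(pairs))

    def __len__(self) -> int:
        return len(self.chroms)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


class TissueExpressionMatrix:
    """Genes x tissues expression values with a designated CNS tissue subset."""

    def __init__(self, gene_ids: Sequence[str], tissue_ids: Sequence[str],
                 expression: np.ndarray, cns_tissues: Sequence[str]):
        self.gene_ids = np.asarray([str(g) for g in gene_ids], dtype=object)
        self.tissue_ids = np.asarray([str(t) for t in tissue_ids], dtype=object)
        self.expression = np.asarray(expression, dtype=float)
        if self.expression.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise ParseError("expression shape does not match ids")
        _check_unique(self.tissue_ids, "tissue id")
        cns = [str(t) for t in cns_tissues]
        unknown = set(cns) - set(self.tissue_ids)
        if unknown:
            raise ParseError(f"CNS tissues not in tissue set: {sorted(unknown)}")
        if not cns:
            raise ParseError("CNS tissue set must be nonempty")
        if len(set(cns)) >= len(self.tissue_ids):
            raise ParseError("CNS tissues must be a strict subset of all tissues")
        self.cns_tissues = tuple(dict.fromkeys(cns))

    def cns_columns(self) -> np.ndarray:
        tset = {t: j for j, t in enumerate(self.tissue_ids)}
        return np.array([tset[t] for t in self.cns_tissues], dtype=np.intp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expression, index=self.gene_ids,
                            columns=self.tissue_ids)
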