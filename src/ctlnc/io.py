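"""Readers, writers and coordinate conventions.

Everything is handled internally as 0-based half-open intervals; conversion
to a format's native convention happens only at the boundary (all formats
used here — BED, bedGraph — are already 0-based half-open).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError

LNCRNA_BIOTYPES = frozenset(
    {
        "3_prime_overlapping_ncRNA",
        "antisense",
        "lincRNA",
        "sense_intronic",
        "sense_overlapping",
        "processed_transcript",
    }
)
KNOWN_BIOTYPES = LNCRNA_BIOTYPES | {"protein_coding", "other"}

RPKM = "RPKM"
NORMALIZED_READ_COUNTS = "normalized_read_counts"
VALID_UNITS = (RPKM, NORMALIZED_READ_COUNTS)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with exon structure and a biotype."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "other"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in KNOWN_BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        prev_end = self.start - 1
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon [{s}, {e}) outside gene span")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted and non-overlapping")
            prev_end = e - 1

    @property
    def is_lncrna(self) -> bool:
        return self.biotype in LNCRNA_BIOTYPES

    @property
    def tss(self) -> int:
        """Strand-aware transcription start (5'-most coordinate)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class Interval:
    """A BED-style interval; strand '.' means strandless."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")


class ExpressionMatrix:
    """Gene-by-sample non-negative expression matrix tagged with its unit."""

    def __init__(self, values: pd.DataFrame, unit: str):
        if unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {unit!r}")
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        arr = values.to_numpy(dtype=float)
        if np.any(~np.isfinite(arr)):
            raise ValueError("non-finite expression value")
        if np.any(arr < 0):
            row = values.index[np.where(arr < 0)[0][0]]
            raise ValueError(f"negative expression value in gene {row!r}")
        self.values = values.astype(float)
        self.unit = unit

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.unit)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.unit)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.unit == other.unit
            and self.values.equals(other.values)
        )


@dataclass
class ScoreTrack:
    """Per-base score track as non-overlapping half-open intervals per chromosome."""

    kind: str
    data: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("phastcons", "phylop"):
            raise ValueError(f"kind must be 'phastcons' or 'phylop', got {self.kind!r}")
        for chrom, segs in self.data.items():
            prev_end = -1
            for s, e, v in sorted(segs):
                if not (0 <= s < e):
                    raise ValueError(f"{chrom}: bad segment [{s}, {e})")
                if s < prev_end:
                    raise ValueError(f"{chrom}: overlapping segments")
                if self.kind == "phastcons" and not (0.0 <= v <= 1.0):
                    raise ValueError(f"{chrom}: phastcons value {v} outside [0, 1]")
                prev_end = e
            self.data[chrom] = sorted(segs)

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        self.data.setdefault(chrom, []).append((start, end, float(value)))

    def finalize(self) -> "ScoreTrack":
        return ScoreTrack(self.kind, self.data)


# ---------------------------------------------------------------------------
# expression TSV


def read_expression(path, unit: str) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError("expression TSV needs a gene column plus samples", path, 1)
        sample_ids = header[1:]
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"ragged row: {len(parts)} fields, expected {len(header)}", path, lineno
                )
            genes.append(parts[0])
            try:
                row = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"non-numeric value: {exc}", path, lineno) from None
            if any(v < 0 for v in row):
                raise ParseError(f"negative value for gene {parts[0]!r}", path, lineno)
            rows.append(row)
    df = pd.DataFrame(rows, index=genes, columns=sample_ids)
    try:
        return ExpressionMatrix(df, unit)
    except ValueError as exc:
        raise ParseError(str(exc), path) from None


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# BED


def read_bed(path, min_fields: int = 3) -> list[Interval]:
    out = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_fields:
                raise ParseError(f"expected >= {min_fields} fields", path, lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-integer coordinate", path, lineno) from None
            if start >= end:
                raise ParseError(f"start {start} >= end {end}", path, lineno)
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(f"bad strand {strand!r}", path, lineno)
            out.append(Interval(parts[0], start, end, name, score, strand))
    return out


def write_bed6(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n")


def read_bed12(path) -> list[GeneModel]:
    """BED12 gene models; the name field carries ``gene_id|biotype``."""
    genes = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError("BED12 needs 12 fields", path, lineno)
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ParseError(f"start {start} >= end {end}", path, lineno)
            name, strand = parts[3], parts[5]
            if strand == ".":
                raise ParseError("gene models require an explicit strand", path, lineno)
            gene_id, _, biotype = name.partition("|")
            n_blocks = int(parts[9])
            sizes = [int(v) for v in parts[10].rstrip(",").split(",")]
            starts = [int(v) for v in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError("blockCount disagrees with block lists", path, lineno)
            exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            try:
                genes.append(
                    GeneModel(gene_id, chrom, start, end, strand, exons, biotype or "other")
                )
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
    return genes


def write_bed12(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}|{g.biotype}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# GTF-lite (gene/exon features with gene_id and gene_type attributes)


def read_gtf_lite(path) -> list[GeneModel]:
    spans: dict[str, dict] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError("GTF needs 9 fields", path, lineno)
            chrom, _, feature, start1, end, _, strand, _, attrs = parts[:9]
            if feature not in ("gene", "exon"):
                continue
            attr = {}
            for item in attrs.rstrip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attr[key] = val.strip().strip('"')
            gid = attr.get("gene_id")
            if gid is None:
                raise ParseError("missing gene_id attribute", path, lineno)
            start = int(start1) - 1  # GTF is 1-based closed
            if start >= int(end):
                raise ParseError("start >= end", path, lineno)
            rec = spans.setdefault(
                gid, {"chrom": chrom, "strand": strand, "biotype": "other", "exons": [], "span": None}
            )
            if feature == "gene":
                rec["span"] = (start, int(end))
                rec["biotype"] = attr.get("gene_type", "other")
            else:
                rec["exons"].append((start, int(end)))
    genes = []
    for gid, rec in spans.items():
        exons = tuple(sorted(rec["exons"]))
        span = rec["span"] or (exons[0][0], exons[-1][1])
        biotype = rec["biotype"] if rec["biotype"] in KNOWN_BIOTYPES else "other"
        genes.append(GeneModel(gid, rec["chrom"], span[0], span[1], rec["strand"], exons, biotype))
    return genes


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, kind: str) -> ScoreTrack:
    track = ScoreTrack(kind)
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError("bedGraph needs 4 fields", path, lineno)
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ParseError(f"start {start} >= end {end}", path, lineno)
            track.add(parts[0], start, end, float(parts[3]))
    return track.finalize()


def write_bedgraph(track: ScoreTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            for s, e, v in track.data[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{_FLOAT_FMT % v}\n")


# ---------------------------------------------------------------------------
# GMT / MAF-lite / clinical / truth JSON


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("GMT line needs name, description and >= 1 gene", path, lineno)
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


MAF_COLUMNS = ["sample_id", "gene", "variant_class"]


def read_maf_lite(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"MAF-lite missing columns {missing}", path)
    return df[MAF_COLUMNS]


def write_maf_lite(df: pd.DataFrame, path) -> None:
    df[MAF_COLUMNS].to_csv(path, sep="\t", index=False)


CLINICAL_COLUMNS = ["sample_id", "age", "gender", "stage", "cancer_type"]


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"clinical table missing columns {missing}", path)
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
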