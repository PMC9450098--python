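"""Readers and writers for the plain-text formats every stage touches.

BED3/BED4 for peaks, summits and TADs; headered TSV for gene tables, sample
sheets, count/expression matrices and DE tables; FASTA (via Biopython) for
peak sequences. Parsing is total and order-preserving: every data line
yields exactly one record or one error naming the line.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .types import CountMatrix, GeneModel, GenomicInterval, SampleInfo, TadDomain

__all__ = [
    "ParseError",
    "SchemaError",
    "parse_interval_file",
    "write_interval_file",
    "parse_gene_table",
    "write_gene_table",
    "parse_sample_sheet",
    "write_sample_sheet",
    "parse_count_matrix",
    "write_count_matrix",
    "parse_de_table",
    "parse_tad_file",
    "read_peak_sequences",
]


class ParseError(ValueError):
    """A malformed line or value, located by file and line number."""


class SchemaError(ValueError):
    """A header/sheet mismatch or missing required column."""


def _data_lines(path: str) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def parse_interval_file(path: str, expect_width_one: bool = False) -> list[GenomicInterval]:
    """Read a BED3/BED4 file into intervals, in file order.

    Column 4, when present, supplies the name; otherwise ``chrom:start-end``
    is synthesized. With ``expect_width_one`` any interval wider than 1 bp
    (i.e. not a summit) raises.
    """
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        name = fields[3] if len(fields) >= 4 else None
        try:
            iv = GenomicInterval(chrom, start, end, name)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if expect_width_one and iv.width != 1:
            raise ParseError(
                f"{path}:{lineno}: expected width-1 summit, got width {iv.width}"
            )
        out.append(iv)
    return out


def write_interval_file(path: str, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


_GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "gene_start", "gene_end"]


def parse_gene_table(path: str) -> list[GeneModel]:
    """Read a headered gene table (one canonical TSS per gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    genes = []
    for row in df.itertuples(index=False):
        try:
            genes.append(
                GeneModel(
                    gene_id=row.gene_id,
                    chrom=row.chrom,
                    tss=int(row.tss),
                    strand=row.strand,
                    gene_start=int(row.gene_start),
                    gene_end=int(row.gene_end),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: gene {row.gene_id!r}: {exc}") from None
    return genes


def write_gene_table(path: str, genes: Sequence[GeneModel]) -> None:
    pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.tss, g.strand, g.gene_start, g.gene_end)
            for g in genes
        ],
        columns=_GENE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def parse_sample_sheet(path: str) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "condition", "replicate", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    samples = []
    for row in df.itertuples(index=False):
        try:
            samples.append(
                SampleInfo(row.sample_id, row.condition, int(row.replicate), row.role)
            )
        except ValueError as exc:
            raise ParseError(f"{path}: sample {row.sample_id!r}: {exc}") from None
    keys = [(s.condition, s.replicate) for s in samples]
    if len(set(keys)) != len(keys):
        raise ParseError(f"{path}: duplicate (condition, replicate) pair")
    return samples


def write_sample_sheet(path: str, samples: Sequence[SampleInfo]) -> None:
    pd.DataFrame(
        [(s.sample_id, s.condition, s.replicate, s.role) for s in samples],
        columns=["sample_id", "condition", "replicate", "role"],
    ).to_csv(path, sep="\t", index=False)


def parse_count_matrix(path: str, sample_sheet: str, units: str = "fragments") -> CountMatrix:
    """Read a row-id x sample TSV and attach sample metadata.

    Every data column header must match a sample_id in the sheet; columns are
    re-ordered to sample-sheet order.
    """
    samples = parse_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sheet_ids = [s.sample_id for s in samples]
    extra = [c for c in df.columns if c not in set(sheet_ids)]
    absent = [s for s in sheet_ids if s not in set(df.columns)]
    if extra or absent:
        raise SchemaError(
            f"{path}: columns do not match sample sheet "
            f"(unknown {extra}, missing {absent})"
        )
    df = df[sheet_ids]
    if df.isna().any().any():
        raise ParseError(f"{path}: non-numeric or missing value in matrix")
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative value in count matrix")
    return CountMatrix(df.index.astype(str).tolist(), samples, df.values, units)


def write_count_matrix(path: str, matrix: CountMatrix, float_format: str = "%.12g") -> None:
    matrix.to_frame().rename_axis("row_id").to_csv(
        path, sep="\t", float_format=float_format
    )


def parse_de_table(path: str) -> pd.DataFrame:
    """Read an external differential-expression table (gene_id, log2fc, qvalue)."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "log2fc", "qvalue"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def parse_tad_file(path: str) -> list[TadDomain]:
    """Read TAD intervals from BED; per-chromosome overlap is rejected."""
    domains = []
    for i, iv in enumerate(parse_interval_file(path)):
        domains.append(TadDomain(iv.chrom, iv.start, iv.end, iv.name or f"tad_{i + 1}"))
    by_chrom: dict[str, list[TadDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom, ds in by_chrom.items():
        ds = sorted(ds, key=lambda d: d.start)
        for a, b in zip(ds, ds[1:]):
            if b.start < a.end:
                raise ParseError(
                    f"{path}: overlapping TADs {a.tad_id}/{b.tad_id} on {chrom}"
                )
    return domains


def read_peak_sequences(path: str) -> dict[str, str]:
    """FASTA keyed by peak id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def ensure_dir(path: str) -> None:
    os.makedirs(path, exist_ok=True)
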