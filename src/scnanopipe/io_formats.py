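"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open; conversion to/from the
1-based conventions of GTF and VCF happens here and only here.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from scipy import io as spio
from scipy import sparse


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_DNA = set("ACGTN")


@dataclass
class RawRead:
    """A raw sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if not set(self.sequence) <= _DNA:
            bad = sorted(set(self.sequence) - _DNA)
            raise ValueError(f"read {self.read_id!r}: non-DNA symbols {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptModel:
    """Ordered, non-overlapping exon intervals (0-based half-open)."""

    transcript_id: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.transcript_id}: empty exon [{start},{end})")
            if start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = end

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """Intron (donor_end, acceptor_start) pairs between consecutive exons."""
        return [
            (self.exons[k][1], self.exons[k + 1][0])
            for k in range(len(self.exons) - 1)
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: no transcripts")
        lo, hi = self.span
        for tx in self.transcripts:
            s, e = tx.span
            if s < lo or e > hi:
                raise ValueError(f"{self.gene_id}/{tx.transcript_id}: exon outside gene span")

    @property
    def exon_union(self) -> list[tuple[int, int]]:
        """Merged union of all transcript exons."""
        ivs = sorted(iv for tx in self.transcripts for iv in tx.exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


@dataclass
class AlignmentRecord:
    """A spliced alignment as exon-like reference blocks (0-based half-open)."""

    query_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    mapq: int = 60

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.blocks:
            if start >= end or start < prev_end:
                raise ValueError(f"{self.query_id}: blocks unsorted/overlapping")
            prev_end = end

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def junctions(self) -> list[tuple[int, int]]:
        return [
            (self.blocks[k][1], self.blocks[k + 1][0])
            for k in range(len(self.blocks) - 1)
        ]


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[RawRead]:
    """Stream RawReads from a plain or gzipped FASTQ file (Phred+33).

    A malformed record raises ValueError naming the (0-based) record index.
    """
    with _open_text(path) as handle:
        index = 0
        parser = SeqIO.parse(handle, "fastq")
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index}: {exc}") from exc
            try:
                yield RawRead(
                    read_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=list(rec.letter_annotations["phred_quality"]),
                )
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index}: {exc}") from exc
            index += 1


def write_fastq(reads: Iterable[RawRead], path) -> int:
    """Write reads as Phred+33 FASTQ (.gz transparent). Returns record count."""
    n = 0
    with _open_text(path, "wt") as out:
        for r in reads:
            qual = "".join(chr(min(q, 93) + 33) for q in r.qualities)
            out.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for k in range(0, len(seq), width):
                out.write(seq[k : k + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path) -> list[GeneModel]:
    """Parse gene models from GTF (1-based inclusive -> 0-based half-open)."""
    cols = [
        "chrom", "source", "feature", "start", "end",
        "score", "strand", "frame", "attributes",
    ]
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=cols,
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []

    def attr(s: str, key: str) -> str | None:
        for part in s.rstrip(";").split(";"):
            part = part.strip()
            if part.startswith(key + " "):
                return part.split(" ", 1)[1].strip().strip('"')
        return None

    genes: dict[str, dict] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_gene: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gid = attr(row.attributes, "gene_id")
        tid = attr(row.attributes, "transcript_id")
        start0, end0 = int(row.start) - 1, int(row.end)  # to half-open
        if row.feature == "gene":
            genes[gid] = {"chrom": row.chrom, "strand": row.strand,
                          "span": (start0, end0)}
        elif row.feature == "transcript":
            if tid is None:
                raise ValueError("transcript feature without transcript_id")
            tx_gene[tid] = gid
            tx_exons.setdefault(tid, [])
        elif row.feature == "exon":
            if tid is None or tid not in tx_gene:
                raise ValueError(
                    f"exon without parent transcript (transcript_id={tid!r})"
                )
            tx_exons[tid].append((start0, end0))

    models: list[GeneModel] = []
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, exons in tx_exons.items():
        by_gene.setdefault(tx_gene[tid], []).append(
            TranscriptModel(tid, sorted(exons))
        )
    for gid, info in genes.items():
        txs = sorted(by_gene.get(gid, []), key=lambda t: t.transcript_id)
        if not txs:
            continue
        models.append(GeneModel(gid, info["chrom"], info["strand"], info["span"], txs))
    return models


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """Emit gene/transcript/exon features, converting back to 1-based inclusive."""
    with _open_text(path, "wt") as out:
        for g in genes:
            a = f'gene_id "{g.gene_id}";'
            out.write(
                f"{g.chrom}\ttoy\tgene\t{g.span[0] + 1}\t{g.span[1]}\t.\t{g.strand}\t.\t{a}\n"
            )
            for tx in g.transcripts:
                ta = f'gene_id "{g.gene_id}"; transcript_id "{tx.transcript_id}";'
                s, e = tx.span
                out.write(
                    f"{g.chrom}\ttoy\ttranscript\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{ta}\n"
                )
                for es, ee in tx.exons:
                    out.write(
                        f"{g.chrom}\ttoy\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{ta}\n"
                    )


# ---------------------------------------------------------------------------
# alignments: SAM/BAM and the truth-TSV dialect
# ---------------------------------------------------------------------------

def _blocks_from_cigar(pos0: int, cigartuples) -> list[tuple[int, int]]:
    """Reference blocks from CIGAR; N splits blocks, D extends them."""
    blocks: list[tuple[int, int]] = []
    cur_start, cur = pos0, pos0
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            cur += length
        elif op == 3:  # N: splice, close block
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += length
            cur_start = cur
        # I, S, H, P consume no reference
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return blocks


def read_alignments(path, known_chroms: set[str] | None = None) -> list[AlignmentRecord]:
    """Read SAM/BAM (via pysam) or the truth-alignment TSV dialect.

    The TSV dialect has columns: query_id, chrom, strand, blocks, mapq with
    blocks encoded as comma-separated "start-end" pairs (0-based half-open).
    """
    path = os.fspath(path)
    records: list[AlignmentRecord] = []
    if path.endswith((".tsv", ".tsv.gz")):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for row in df.itertuples(index=False):
            blocks = [
                (int(p.split("-")[0]), int(p.split("-")[1]))
                for p in str(row.blocks).split(",")
            ]
            records.append(
                AlignmentRecord(str(row.query_id), row.chrom, row.strand, blocks,
                                int(row.mapq))
            )
    else:
        mode = "rb" if path.endswith(".bam") else "r"
        with pysam.AlignmentFile(path, mode, check_sq=False) as af:
            for aln in af.fetch(until_eof=True):
                if aln.is_unmapped:
                    continue
                records.append(
                    AlignmentRecord(
                        aln.query_name,
                        aln.reference_name,
                        "-" if aln.is_reverse else "+",
                        _blocks_from_cigar(aln.reference_start, aln.cigartuples),
                        aln.mapping_quality,
                    )
                )
    if known_chroms is not None:
        for rec in records:
            if rec.chrom not in known_chroms:
                raise ValueError(f"unknown chromosome {rec.chrom!r} in {path}")
    return records


def write_alignments_tsv(records: Sequence[AlignmentRecord], path) -> None:
    rows = [
        {
            "query_id": r.query_id,
            "chrom": r.chrom,
            "strand": r.strand,
            "blocks": ",".join(f"{s}-{e}" for s, e in r.blocks),
            "mapq": r.mapq,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["query_id", "chrom", "strand", "blocks", "mapq"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# count matrices (MatrixMarket + TSV sidecars)
# ---------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, prefix) -> None:
    """Write a features x cells DataFrame as <prefix>.mtx plus sidecar TSVs."""
    prefix = os.fspath(prefix)
    spio.mmwrite(prefix + ".mtx", sparse.csr_matrix(matrix.to_numpy(dtype=float)))
    pd.Series(matrix.index).to_csv(prefix + ".features.tsv", sep="\t",
                                   index=False, header=False)
    pd.Series(matrix.columns).to_csv(prefix + ".barcodes.tsv", sep="\t",
                                     index=False, header=False)


def read_matrix(prefix) -> pd.DataFrame:
    prefix = os.fspath(prefix)
    m = spio.mmread(prefix + ".mtx").toarray()
    features = pd.read_csv(prefix + ".features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(prefix + ".barcodes.tsv", sep="\t", header=None)[0].tolist()
    return pd.DataFrame(m, index=features, columns=barcodes)


# ---------------------------------------------------------------------------
# barcode lists
# ---------------------------------------------------------------------------

def write_barcode_list(df: pd.DataFrame, path) -> None:
    """TSV of per-read or per-CB barcode records (gzip by extension)."""
    df.to_csv(path, sep="\t", index=False)


def read_barcode_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cb": str, "umi": str})


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(variants, cells: Sequence[str], path, reference_name: str = "toy") -> None:
    """Write per-cell genotypes: 0/0 wild-type, 0/1 mutant, ./. missing.

    ``variants`` is an iterable of objects with attributes chrom, pos
    (0-based), ref, alt, states (cell -> 'mutant'|'wild-type'|'missing'),
    depths (cell -> int).
    """
    with _open_text(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##reference={reference_name}\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Consensus molecule depth">\n')
        chroms = sorted({v.chrom for v in variants})
        for c in chroms:
            out.write(f"##contig=<ID={c}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(cells) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            fields = [v.chrom, str(v.pos + 1), ".", v.ref, v.alt, ".", "PASS", ".", "GT:DP"]
            for cell in cells:
                state = v.states.get(cell, "missing")
                depth = int(v.depths.get(cell, 0))
                gt = {"mutant": "0/1", "wild-type": "0/0", "missing": "./."}[state]
                fields.append(f"{gt}:{depth}")
            out.write("\t".join(fields) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF back into a long DataFrame (one row per variant x cell)."""
    rows = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        cells = list(vf.header.samples)
        for rec in vf:
            for alt in rec.alts or ():
                for cell in cells:
                    sample = rec.samples[cell]
                    gt = sample.get("GT")
                    if gt is None or gt == (None, None):
                        state = "missing"
                    elif 1 in gt:
                        state = "mutant"
                    else:
                        state = "wild-type"
                    rows.append(
                        {
                            "chrom": rec.chrom,
                            "pos": rec.pos - 1,  # back to 0-based
                            "ref": rec.ref,
                            "alt": alt,
                            "cell": cell,
                            "state": state,
                            "depth": sample.get("DP", 0) or 0,
                        }
                    )
    return pd.DataFrame(rows)
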