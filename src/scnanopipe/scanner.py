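"""Adapter scanning: locate 5' R1 and 3' TSO adapters, orient reads, and
extract the cell barcode (CB), UMI and insert.

The library construct is R1-adapter + 16nt CB + 12nt UMI + polyT + cDNA
insert + TSO adapter; reads may arrive reverse-complemented. Adapters are
located by alignment with BLAST-like scoring (match +2, mismatch -3, gap
open -5, gap extend -2) and accepted at >= 70% identity. Inserts shorter
than 200 bp are rejected.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import Align

from .io_formats import RawRead, write_fastq, write_barcode_list

R1_ADAPTER = "CTACACGACGCTCTTCCGATCT"
TSO_ADAPTER = "AAGCAGTGGTATCAACGCAGAGTACAT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AdapterConfig:
    r1_adapter: str = R1_ADAPTER
    tso_adapter: str = TSO_ADAPTER
    cb_len: int = 16
    umi_len: int = 12
    min_identity: float = 0.70
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_insert_len: int = 200
    search_window: int = 100
    polyt_tolerance: int = 10  # allow 1 non-T per this many T's when trimming

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.cb_len <= 0 or self.umi_len <= 0:
            raise ValueError("cb_len and umi_len must be positive")


@dataclass
class AdapterHit:
    start: int      # interval on the searched sequence, 0-based half-open
    end: int
    identity: float
    score: float


@dataclass
class TaggedRead:
    read_id: str
    raw_cb: str
    raw_umi: str
    insert_seq: str
    insert_quals: list[int]
    orientation: str  # "forward" | "reverse-complemented"
    r1_identity: float
    tso_identity: float


@dataclass
class Rejection:
    read_id: str
    reason: str  # no_r1 | no_tso | short_insert | short_read


@dataclass
class QCReport:
    length_histogram: dict[int, int]
    head_quality: list[float]  # mean Phred over first <=100 positions
    tail_quality: list[float]  # mean Phred over last <=100 positions
    n_reads: int

    def length_table(self) -> pd.DataFrame:
        items = sorted(self.length_histogram.items())
        return pd.DataFrame(items, columns=["length", "count"])


def _make_aligner(config: AdapterConfig) -> Align.PairwiseAligner:
    """Semi-global aligner: the adapter aligns end to end, the target's
    flanks are free. Internal gaps on either side are penalised."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.match
    aligner.mismatch_score = config.mismatch
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    # free end gaps on the target only (unaligned window flanks cost nothing)
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


def locate_adapter(
    sequence: str,
    adapter: str,
    config: AdapterConfig | None = None,
    end: str = "5p",
) -> AdapterHit | None:
    """Find the adapter in the terminal search window of ``sequence``.

    Identity = matches / alignment columns of the adapter's aligned core
    (gap columns included, free target flanks excluded). Returns None if
    identity < min_identity or no positive-score alignment exists.
    """
    if config is None:
        config = AdapterConfig(r1_adapter=adapter)
    if not sequence:
        return None
    window = config.search_window + len(adapter)
    if end == "5p":
        target = sequence[:window]
        offset = 0
    else:
        target = sequence[-window:]
        offset = len(sequence) - len(target)
    aligner = _make_aligner(config)
    try:
        alignments = aligner.align(target, adapter)
        best = alignments[0]
    except (ValueError, IndexError, OverflowError):
        return None
    if best.score <= 0:
        return None

    t_ranges, q_ranges = best.aligned
    if len(t_ranges) == 0:
        return None
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(t_ranges, q_ranges):
        tseg, qseg = target[ts:te], adapter[qs:qe]
        matches += sum(a == b for a, b in zip(tseg, qseg))
        columns += te - ts
    # internal gap columns between aligned blocks
    for k in range(len(t_ranges) - 1):
        columns += (t_ranges[k + 1][0] - t_ranges[k][1]) + (
            q_ranges[k + 1][0] - q_ranges[k][1]
        )
    # adapter bases hanging off the alignment (query end gaps) count as columns
    columns += q_ranges[0][0] + (len(adapter) - q_ranges[-1][1])
    if columns == 0:
        return None
    identity = matches / columns
    if identity < config.min_identity:
        return None
    return AdapterHit(
        start=offset + int(t_ranges[0][0]),
        end=offset + int(t_ranges[-1][1]),
        identity=identity,
        score=float(best.score),
    )


def _trim_polyt(seq: str, start: int, stop: int, tolerance: int) -> int:
    """Return the index just past the polyT tract starting at ``start``.

    A non-T base is absorbed only if at least ``tolerance`` T's have been
    consumed since the previous non-T (one mismatch per `tolerance` T's).
    """
    pos = start
    ts_since_miss = 0
    while pos < stop:
        if seq[pos] == "T":
            ts_since_miss += 1
            pos += 1
        elif ts_since_miss >= tolerance and pos + 1 < stop and seq[pos + 1] == "T":
            ts_since_miss = 0
            pos += 1
        else:
            break
    return pos


def scan_read(read: RawRead, config: AdapterConfig | None = None) -> TaggedRead | Rejection:
    """Orient a read and extract CB/UMI/insert, or reject it with a reason."""
    if config is None:
        config = AdapterConfig()
    # too short to even hold both adapters plus CB and UMI
    min_len = (
        len(config.r1_adapter) + config.cb_len + config.umi_len
        + len(config.tso_adapter)
    )
    if len(read) < min_len:
        return Rejection(read.read_id, "short_read")

    # evaluate both orientations; a spurious R1-like match in one must not
    # mask a complete adapter pair in the other
    candidates = []
    saw_r1 = False
    for orientation in ("forward", "reverse-complemented"):
        if orientation == "forward":
            seq, quals = read.sequence, read.qualities
        else:
            seq, quals = revcomp(read.sequence), read.qualities[::-1]
        r1 = locate_adapter(seq, config.r1_adapter, config, end="5p")
        if r1 is None:
            continue
        saw_r1 = True
        tso = locate_adapter(seq, config.tso_adapter, config, end="3p")
        if tso is None:
            continue
        candidates.append((r1.score + tso.score, orientation, seq, quals, r1, tso))
    if not candidates:
        return Rejection(read.read_id, "no_tso" if saw_r1 else "no_r1")
    _, orientation, seq, quals, r1, tso = max(candidates, key=lambda c: c[0])
    cb_start = r1.end
    umi_start = cb_start + config.cb_len
    umi_end = umi_start + config.umi_len
    if umi_end >= tso.start:
        return Rejection(read.read_id, "short_insert")
    raw_cb = seq[cb_start:umi_start]
    raw_umi = seq[umi_start:umi_end]
    insert_start = _trim_polyt(seq, umi_end, tso.start, config.polyt_tolerance)
    insert_seq = seq[insert_start : tso.start]
    if len(insert_seq) < config.min_insert_len:
        return Rejection(read.read_id, "short_insert")
    return TaggedRead(
        read_id=read.read_id,
        raw_cb=raw_cb,
        raw_umi=raw_umi,
        insert_seq=insert_seq,
        insert_quals=quals[insert_start : tso.start],
        orientation=orientation,
        r1_identity=r1.identity,
        tso_identity=tso.identity,
    )


def scan_reads(
    reads: Iterable[RawRead], config: AdapterConfig | None = None
) -> tuple[list[TaggedRead], collections.Counter]:
    """Scan a read stream; returns accepted TaggedReads and rejection counts."""
    if config is None:
        config = AdapterConfig()
    accepted: list[TaggedRead] = []
    rejections: collections.Counter = collections.Counter()
    for read in reads:
        result = scan_read(read, config)
        if isinstance(result, TaggedRead):
            accepted.append(result)
        else:
            rejections[result.reason] += 1
    return accepted, rejections


def scan_file(
    fastq_path,
    out_barcodes,
    out_fastq,
    config: AdapterConfig | None = None,
) -> collections.Counter:
    """File-level scanner: emits the barcode observation TSV
    (read_id, cb, umi) and the oriented, filtered insert FASTQ."""
    from .io_formats import read_fastq

    tagged, rejections = scan_reads(read_fastq(fastq_path), config)
    df = pd.DataFrame(
        [(t.read_id, t.raw_cb, t.raw_umi) for t in tagged],
        columns=["read_id", "cb", "umi"],
    )
    write_barcode_list(df, out_barcodes)
    write_fastq(
        (RawRead(t.read_id, t.insert_seq, t.insert_quals) for t in tagged),
        out_fastq,
    )
    rejections["accepted"] = len(tagged)
    return rejections


def nanoqc(reads: Iterable[RawRead], window: int = 100) -> QCReport:
    """Read-length histogram and terminal per-position mean quality."""
    hist: collections.Counter = collections.Counter()
    head_sum = np.zeros(window)
    head_n = np.zeros(window)
    tail_sum = np.zeros(window)
    tail_n = np.zeros(window)
    n = 0
    for read in reads:
        n += 1
        hist[len(read)] += 1
        q = np.asarray(read.qualities, dtype=float)
        k = min(window, len(q))
        head_sum[:k] += q[:k]
        head_n[:k] += 1
        tail_sum[:k] += q[-k:][::-1]  # positions counted from the 3' end
        tail_n[:k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        head = np.where(head_n > 0, head_sum / np.maximum(head_n, 1), np.nan)
        tail = np.where(tail_n > 0, tail_sum / np.maximum(tail_n, 1), np.nan)
    return QCReport(
        length_histogram=dict(hist),
        head_quality=head.tolist(),
        tail_quality=tail.tolist(),
        n_reads=n,
    )
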