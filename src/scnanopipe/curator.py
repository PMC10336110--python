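"""Molecule curation: positional read clustering, UMI merging within 2
Levenshtein distances, and consensus construction over duplicate reads.

Reads of one cell that align to the same genomic region (start coordinates
chained within 5 bp, same chromosome and strand) are clustered; within a
cluster, UMIs within 2 LD are merged one-directionally toward the UMI with
most supporting reads; each curated UMI group is collapsed into a single
consensus molecule.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np

from .io_formats import AlignmentRecord, RawRead
from .assigner import levenshtein


@dataclass
class ClusterMember:
    read_id: str
    umi: str
    start: int


@dataclass
class ReadCluster:
    cell: str
    chrom: str
    strand: str
    anchor: tuple[int, int]  # (min start, max start) of members
    members: list[ClusterMember]


@dataclass
class Molecule:
    cell: str
    umi: str                    # curated (representative) UMI
    sequence: str
    qualities: list[int]
    support: int
    chrom: str
    strand: str
    anchor: tuple[int, int]
    member_read_ids: list[str]

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("molecule support must be >= 1")


def cluster_by_position(
    cell: str,
    alignments: Sequence[AlignmentRecord],
    umis: Mapping[str, str],
    tol: int = 5,
) -> list[ReadCluster]:
    """Single-linkage chaining of alignment starts within ``tol`` bp,
    keyed by (chrom, strand). ``umis`` maps read id -> raw UMI."""
    ordered = sorted(alignments, key=lambda a: (a.chrom, a.strand, a.start, a.query_id))
    clusters: list[ReadCluster] = []
    current: list[ClusterMember] = []
    cur_key: tuple[str, str] | None = None
    last_start = None

    def close() -> None:
        if current:
            clusters.append(
                ReadCluster(
                    cell=cell,
                    chrom=cur_key[0],
                    strand=cur_key[1],
                    anchor=(current[0].start, current[-1].start),
                    members=list(current),
                )
            )

    for aln in ordered:
        key = (aln.chrom, aln.strand)
        member = ClusterMember(aln.query_id, umis[aln.query_id], aln.start)
        if cur_key == key and last_start is not None and aln.start - last_start <= tol:
            current.append(member)
        else:
            close()
            current = [member]
            cur_key = key
        last_start = aln.start
    close()
    return clusters


def curate_umis(
    umis: Sequence[str], max_ld: int = 2
) -> dict[str, list[int]]:
    """Group UMIs of one positional cluster: merge one-directionally toward
    the UMI with most supporting reads (same greedy rule as the CB merge).

    Returns curated UMI -> member indices into ``umis``.
    """
    by_umi: dict[str, list[int]] = collections.defaultdict(list)
    for idx, u in enumerate(umis):
        by_umi[u].append(idx)
    order = sorted(by_umi, key=lambda u: (-len(by_umi[u]), u))
    retained: list[str] = []
    groups: dict[str, list[int]] = {}
    for u in order:
        absorber = None
        for cand in retained:
            if levenshtein(u, cand, k=max_ld) <= max_ld:
                absorber = cand
                break
        if absorber is None:
            retained.append(u)
            groups[u] = list(by_umi[u])
        else:
            groups[absorber].extend(by_umi[u])
    return groups


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def build_consensus(
    sequences: Sequence[str], qualities: Sequence[Sequence[int]]
) -> tuple[str, list[int]]:
    """Collapse duplicate reads of one molecule into a consensus sequence.

    support 1: the read itself. support 2: the read with the higher mean
    base quality. support >= 3: center-star progressive alignment around
    the highest-mean-quality backbone, per-column majority vote over
    {A,C,G,T,N,-}; ties broken by summed base quality, then alphabetically;
    a gap majority deletes the column.
    """
    n = len(sequences)
    if n == 0:
        raise ValueError("no reads to collapse")
    mean_q = [float(np.mean(q)) if len(q) else 0.0 for q in qualities]
    if n == 1:
        return sequences[0], list(qualities[0])
    if n == 2:
        best = max(range(2), key=lambda j: (mean_q[j], -j))
        return sequences[best], list(qualities[best])

    backbone_idx = max(range(n), key=lambda j: (mean_q[j], -j))
    backbone = sequences[backbone_idx]
    L = len(backbone)

    # votes on backbone columns: col -> symbol -> (count, summed quality)
    match_votes: list[dict[str, list[float]]] = [
        collections.defaultdict(lambda: [0, 0.0]) for _ in range(L)
    ]
    # insertion columns keyed by (backbone position, offset)
    ins_votes: dict[tuple[int, int], dict[str, list[float]]] = collections.defaultdict(
        lambda: collections.defaultdict(lambda: [0, 0.0])
    )
    ins_seen: collections.Counter = collections.Counter()  # readers per ins key

    def add_read(seq: str, qual: Sequence[int]) -> None:
        if len(seq) == len(backbone):
            # equal length implies substitution-only differences (or a rare
            # balanced ins+del); column-wise voting avoids spurious indel
            # columns from co-optimal edit paths
            for pos, base in enumerate(seq):
                v = match_votes[pos][base]
                v[0] += 1
                v[1] += qual[pos]
            return
        res = edlib.align(seq, backbone, task="path", mode="NW")
        bpos = 0  # backbone (target) position
        spos = 0  # read (query) position
        for length, op in _cigar_ops(res["cigar"]):
            if op in ("=", "X", "M"):
                for k in range(length):
                    v = match_votes[bpos + k][seq[spos + k]]
                    v[0] += 1
                    v[1] += qual[spos + k]
                bpos += length
                spos += length
            elif op == "D":  # gap in read: vote for deletion of backbone column
                for k in range(length):
                    v = match_votes[bpos + k]["-"]
                    v[0] += 1
                bpos += length
            elif op == "I":  # insertion relative to backbone
                for k in range(length):
                    key = (bpos, k)
                    ins_seen[key] += 1
                    v = ins_votes[key][seq[spos + k]]
                    v[0] += 1
                    v[1] += qual[spos + k]
                spos += length

    for j in range(n):
        add_read(sequences[j], qualities[j])

    def winner(votes: dict[str, list[float]], n_readers: int):
        # readers that did not vote at an insertion column vote gap
        table = {sym: (c, q) for sym, (c, q) in votes.items()}
        gap_c, gap_q = table.get("-", (0, 0.0))
        gap_c += n_readers - sum(c for c, _ in votes.values())
        table["-"] = (gap_c, gap_q)
        return max(table.items(), key=lambda kv: (kv[1][0], kv[1][1], -ord(kv[0][0])))

    out_seq: list[str] = []
    out_qual: list[int] = []

    def emit(votes, n_readers):
        sym, (count, qsum) = winner(votes, n_readers)
        if sym != "-":
            out_seq.append(sym)
            out_qual.append(min(int(round(qsum / max(count, 1))), 60))

    for pos in range(L + 1):
        for k in sorted(k for (p, k) in ins_votes if p == pos):
            emit(ins_votes[(pos, k)], n)
        if pos < L:
            emit(match_votes[pos], n)
    return "".join(out_seq), out_qual


def curate_cell(
    cell: str,
    alignments: Sequence[AlignmentRecord],
    reads: Mapping[str, RawRead],
    umis: Mapping[str, str],
    tol: int = 5,
    umi_max_ld: int = 2,
) -> list[Molecule]:
    """Full per-cell curation: cluster -> curate UMIs -> consensus.

    ``reads`` maps read id -> oriented insert RawRead; ``umis`` maps read
    id -> raw UMI. One Molecule per (cluster, curated UMI).
    """
    molecules: list[Molecule] = []
    for cluster in cluster_by_position(cell, alignments, umis, tol=tol):
        member_umis = [m.umi for m in cluster.members]
        groups = curate_umis(member_umis, max_ld=umi_max_ld)
        for curated_umi in sorted(groups):
            idxs = groups[curated_umi]
            read_ids = [cluster.members[k].read_id for k in idxs]
            seqs = [reads[rid].sequence for rid in read_ids]
            quals = [reads[rid].qualities for rid in read_ids]
            cons_seq, cons_qual = build_consensus(seqs, quals)
            molecules.append(
                Molecule(
                    cell=cell,
                    umi=curated_umi,
                    sequence=cons_seq,
                    qualities=cons_qual,
                    support=len(read_ids),
                    chrom=cluster.chrom,
                    strand=cluster.strand,
                    anchor=cluster.anchor,
                    member_read_ids=sorted(read_ids),
                )
            )
    return molecules
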