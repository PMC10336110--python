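"""Gene and isoform assignment of consensus molecules and count matrices.

Genes are assigned by maximal exonic base overlap (requiring >= 50% of
aligned bases within the winning gene's span); isoforms by exon-chain
compatibility: every internal junction of the molecule must match a
transcript junction within a tolerance, and the molecule's junction chain
must be a contiguous sub-chain of the transcript's (truncation-tolerant at
both termini). One molecule contributes one count, split uniformly across
compatible transcripts.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, GeneModel, TranscriptModel


def _overlap(blocks_a: Sequence[tuple[int, int]], blocks_b: Sequence[tuple[int, int]]) -> int:
    """Total overlap (bases) between two sorted interval lists."""
    total = 0
    i = j = 0
    while i < len(blocks_a) and j < len(blocks_b):
        s = max(blocks_a[i][0], blocks_b[j][0])
        e = min(blocks_a[i][1], blocks_b[j][1])
        if e > s:
            total += e - s
        if blocks_a[i][1] < blocks_b[j][1]:
            i += 1
        else:
            j += 1
    return total


def assign_gene(
    alignment: AlignmentRecord,
    genes: Sequence[GeneModel],
    min_frac: float = 0.5,
    stranded: bool = False,
    allow_intronic: bool = True,
) -> str | None:
    """Winning gene by maximal exonic overlap; ties -> unassigned.

    Requires >= ``min_frac`` of aligned bases within the gene span. If no
    gene has exonic overlap and ``allow_intronic``, a gene whose span
    contains >= min_frac of the aligned bases wins (pre-mRNA molecules).
    """
    aligned = alignment.aligned_length
    exonic: list[tuple[int, str]] = []
    spanic: list[tuple[int, str]] = []
    for g in genes:
        if g.chrom != alignment.chrom:
            continue
        if stranded and g.strand != alignment.strand:
            continue
        span_ov = _overlap(alignment.blocks, [g.span])
        if span_ov == 0:
            continue
        ex_ov = _overlap(alignment.blocks, g.exon_union)
        if ex_ov > 0 and span_ov >= min_frac * aligned:
            exonic.append((ex_ov, g.gene_id))
        elif span_ov >= min_frac * aligned:
            spanic.append((span_ov, g.gene_id))
    for candidates in (exonic, spanic if allow_intronic else []):
        if not candidates:
            continue
        candidates.sort(key=lambda t: (-t[0], t[1]))
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            return None  # exact tie -> unassigned
        return candidates[0][1]
    return None


def _junction_matches(j_mol: tuple[int, int], j_tx: tuple[int, int], tol: int) -> bool:
    return abs(j_mol[0] - j_tx[0]) <= tol and abs(j_mol[1] - j_tx[1]) <= tol


def _compatible(
    blocks: Sequence[tuple[int, int]],
    tx: TranscriptModel,
    tol: int,
) -> bool:
    """Exon-chain compatibility, truncation-tolerant at both termini."""
    mol_j = [
        (blocks[k][1], blocks[k + 1][0]) for k in range(len(blocks) - 1)
    ]
    tx_j = tx.junctions
    if not mol_j:
        # mono-exon molecule: must lie within one exon of the transcript
        s, e = blocks[0][0], blocks[-1][1]
        return any(es - tol <= s and e <= ee + tol for es, ee in tx.exons)
    if len(mol_j) > len(tx_j):
        return False
    # the molecule's junctions must match a contiguous run of tx junctions
    for offset in range(len(tx_j) - len(mol_j) + 1):
        if all(
            _junction_matches(mol_j[k], tx_j[offset + k], tol)
            for k in range(len(mol_j))
        ):
            # terminal blocks must not extend past the flanking exons
            s, e = blocks[0][0], blocks[-1][1]
            first_exon = tx.exons[offset]
            last_exon = tx.exons[offset + len(mol_j)]
            if s >= first_exon[0] - tol and e <= last_exon[1] + tol:
                return True
    return False


def assign_isoform(
    alignment: AlignmentRecord,
    gene: GeneModel,
    junction_tol: int = 10,
) -> dict[str, float]:
    """Fractional transcript counts for a gene-assigned molecule.

    One count split uniformly across compatible transcripts; empty dict if
    none are compatible (the molecule stays gene-level only).
    """
    compatible = [
        tx.transcript_id
        for tx in gene.transcripts
        if _compatible(alignment.blocks, tx, junction_tol)
    ]
    if not compatible:
        return {}
    share = 1.0 / len(compatible)
    return {tid: share for tid in compatible}


@dataclass
class QuantResult:
    gene_matrix: pd.DataFrame        # genes x cells, integer molecule counts
    isoform_matrix: pd.DataFrame     # transcripts x cells, fractional
    per_cell_genes: dict[str, int]   # distinct genes per cell
    unassigned: int


def build_matrices(
    molecule_assignments: Sequence[tuple[str, str | None, dict[str, float]]],
    cells: Sequence[str] | None = None,
) -> QuantResult:
    """Aggregate (cell, gene, {transcript: fraction}) molecule assignments.

    Gene counts are molecule (UMI) counts; isoform counts are fractional and
    per gene sum to at most the gene count.
    """
    gene_counts: collections.Counter = collections.Counter()
    iso_counts: collections.defaultdict = collections.defaultdict(float)
    genes_per_cell: dict[str, set] = collections.defaultdict(set)
    unassigned = 0
    seen_cells: list[str] = []
    seen_set: set[str] = set()
    for cell, gene, iso in molecule_assignments:
        if cell not in seen_set:
            seen_set.add(cell)
            seen_cells.append(cell)
        if gene is None:
            unassigned += 1
            continue
        gene_counts[(gene, cell)] += 1
        genes_per_cell[cell].add(gene)
        for tid, frac in iso.items():
            iso_counts[(tid, cell)] += frac

    cols = list(cells) if cells is not None else sorted(seen_cells)
    genes = sorted({g for g, _ in gene_counts})
    tids = sorted({t for t, _ in iso_counts})
    gm = pd.DataFrame(0, index=genes, columns=cols, dtype=int)
    for (g, c), n in gene_counts.items():
        if c in gm.columns:
            gm.loc[g, c] = n
    im = pd.DataFrame(0.0, index=tids, columns=cols, dtype=float)
    for (t, c), n in iso_counts.items():
        if c in im.columns:
            im.loc[t, c] = n
    per_cell = {c: len(genes_per_cell.get(c, ())) for c in cols}
    return QuantResult(gm, im, per_cell, unassigned)
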