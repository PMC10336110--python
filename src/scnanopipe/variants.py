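"""Transcriptome-wide SNV calling from consensus molecules.

Consensus molecules are piled up against the reference (substitutions
only); a candidate variant needs at least two supporting consensus
molecules across all cells; candidates are filtered by cellular prevalence
(>= 1% of covered cells overall, or >= 5% within at least one cell type);
surviving variants are classified germline (> 90% of covered cells mutant)
versus somatic. Wild-type (covered, no alt) is distinguished from missing
(no coverage).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .curator import Molecule, _cigar_ops
from .io_formats import AlignmentRecord, write_vcf

_BASES = ("A", "C", "G", "T")


@dataclass
class PileupColumn:
    chrom: str
    pos: int                 # 0-based
    ref: str
    cell_base_counts: dict[str, collections.Counter]  # cell -> base -> molecules

    def total(self, base: str) -> int:
        return sum(c[base] for c in self.cell_base_counts.values())

    def depth(self, cell: str) -> int:
        return sum(self.cell_base_counts.get(cell, collections.Counter()).values())


@dataclass
class Variant:
    chrom: str
    pos: int                 # 0-based
    ref: str
    alt: str
    states: dict[str, str]   # cell -> mutant | wild-type | missing
    depths: dict[str, int]
    alt_depths: dict[str, int]
    total_support: int
    label: str | None = None  # germline | somatic

    @property
    def covered_cells(self) -> list[str]:
        return [c for c, s in self.states.items() if s != "missing"]

    @property
    def mutant_cells(self) -> list[str]:
        return [c for c, s in self.states.items() if s == "mutant"]


def pileup(
    molecules: Sequence[Molecule],
    alignments: Mapping[str, AlignmentRecord],
    reference: Mapping[str, str],
) -> list[PileupColumn]:
    """Pile consensus molecules up against the reference.

    ``alignments`` maps a molecule key (cell + '/' + umi) to its spliced
    alignment. Each molecule is globally aligned to the spliced reference
    of its blocks so that indels in the consensus do not shift downstream
    bases; only substitution columns (= and X) are counted. Counts are
    molecules, not raw reads.
    """
    columns: dict[tuple[str, int], dict[str, collections.Counter]] = (
        collections.defaultdict(lambda: collections.defaultdict(collections.Counter))
    )
    for mol in molecules:
        key = f"{mol.cell}/{mol.umi}"
        aln = alignments.get(key)
        if aln is None:
            continue
        if aln.chrom not in reference:
            raise ValueError(f"alignment chrom {aln.chrom!r} not in reference")
        ref_seq = "".join(reference[aln.chrom][s:e] for s, e in aln.blocks)
        coords = np.concatenate(
            [np.arange(s, e) for s, e in aln.blocks]
        )
        res = edlib.align(mol.sequence, ref_seq, task="path", mode="NW")
        rpos = qpos = 0
        for length, op in _cigar_ops(res["cigar"]):
            if op in ("=", "X", "M"):
                for k in range(length):
                    base = mol.sequence[qpos + k]
                    if base in _BASES:
                        g = int(coords[rpos + k])
                        columns[(aln.chrom, g)][mol.cell][base] += 1
                rpos += length
                qpos += length
            elif op == "D":
                rpos += length
            elif op == "I":
                qpos += length
    out = []
    for (chrom, pos) in sorted(columns):
        out.append(
            PileupColumn(
                chrom=chrom,
                pos=pos,
                ref=reference[chrom][pos],
                cell_base_counts=dict(columns[(chrom, pos)]),
            )
        )
    return out


def call_candidates(
    pileups: Iterable[PileupColumn],
    cells: Sequence[str],
    min_support: int = 2,
    per_cell_support: int = 1,
) -> list[Variant]:
    """Candidate variants: alt alleles with >= min_support consensus
    molecules summed across all cells. Each alt of a tri-allelic column is
    evaluated independently. Per-cell state: mutant iff >= per_cell_support
    alt molecules; wild-type iff covered with no alt; missing otherwise."""
    variants: list[Variant] = []
    for col in pileups:
        for alt in _BASES:
            if alt == col.ref:
                continue
            support = col.total(alt)
            if support < min_support:
                continue
            states: dict[str, str] = {}
            depths: dict[str, int] = {}
            alt_depths: dict[str, int] = {}
            for cell in cells:
                depth = col.depth(cell)
                alt_n = col.cell_base_counts.get(cell, collections.Counter())[alt]
                depths[cell] = depth
                alt_depths[cell] = alt_n
                if depth == 0:
                    states[cell] = "missing"
                elif alt_n >= per_cell_support:
                    states[cell] = "mutant"
                else:
                    states[cell] = "wild-type"
            variants.append(
                Variant(col.chrom, col.pos, col.ref, alt,
                        states, depths, alt_depths, support)
            )
    return variants


def consensus_filter(
    candidates: Sequence[Variant],
    cell_types: Mapping[str, str],
    all_cell_frac: float = 0.01,
    type_frac: float = 0.05,
) -> list[Variant]:
    """Prevalence filter: retain a variant iff its mutant fraction over all
    covered cells >= all_cell_frac, OR its mutant fraction within at least
    one cell type (covered cells of that type) >= type_frac."""
    kept = []
    for v in candidates:
        covered = v.covered_cells
        if not covered:
            continue
        mutant = set(v.mutant_cells)
        if len(mutant) / len(covered) >= all_cell_frac:
            kept.append(v)
            continue
        by_type_cov: collections.Counter = collections.Counter()
        by_type_mut: collections.Counter = collections.Counter()
        for c in covered:
            t = cell_types[c]
            by_type_cov[t] += 1
            if c in mutant:
                by_type_mut[t] += 1
        if any(
            by_type_mut[t] / by_type_cov[t] >= type_frac for t in by_type_cov
        ):
            kept.append(v)
    return kept


def classify_germline_somatic(variants: Sequence[Variant], threshold: float = 0.90) -> None:
    """Label each variant in place: germline iff mutant fraction among
    covered cells > threshold, else somatic."""
    for v in variants:
        covered = v.covered_cells
        frac = len(v.mutant_cells) / len(covered) if covered else 0.0
        v.label = "germline" if frac > threshold else "somatic"


def variant_state_frame(variants: Sequence[Variant], cells: Sequence[str]) -> pd.DataFrame:
    """Long-format per-variant, per-cell state/depth table."""
    rows = []
    for v in variants:
        for cell in cells:
            rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "cell": cell,
                    "state": v.states.get(cell, "missing"),
                    "depth": v.depths.get(cell, 0),
                    "alt_depth": v.alt_depths.get(cell, 0),
                    "label": v.label,
                }
            )
    return pd.DataFrame(rows)


def export_vcf(variants: Sequence[Variant], cells: Sequence[str], path) -> None:
    write_vcf(variants, cells, path)


def variants_from_counts(
    depth: pd.DataFrame,
    alt: pd.DataFrame,
    chrom: str = "sim",
    ref: str = "A",
    alt_base: str = "G",
    min_support: int = 2,
    per_cell_support: int = 1,
) -> list[Variant]:
    """Build candidate variants from locus x cell depth/alt-count tables
    (the simulator's compact representation). Rows are loci (the row index
    gives ``pos``), columns are cells; the same support rules apply."""
    variants = []
    cells = list(depth.columns)
    d = depth.to_numpy()
    a = alt.to_numpy()
    for r, pos in enumerate(depth.index):
        support = int(a[r].sum())
        if support < min_support:
            continue
        states = {}
        depths = {}
        alt_depths = {}
        for j, cell in enumerate(cells):
            depths[cell] = int(d[r, j])
            alt_depths[cell] = int(a[r, j])
            if d[r, j] == 0:
                states[cell] = "missing"
            elif a[r, j] >= per_cell_support:
                states[cell] = "mutant"
            else:
                states[cell] = "wild-type"
        variants.append(
            Variant(chrom, int(pos), ref, alt_base, states, depths, alt_depths, support)
        )
    return variants
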