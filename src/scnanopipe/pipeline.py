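"""End-to-end pipeline driver.

Stage order: NanoQC -> Scanner -> Assigner (cell calling + deconvolution)
-> alignment lookup -> Curator (UMI curation + consensus) -> re-alignment
-> Reporter (gene/isoform matrices) -> gene-count filter (Cr4) -> SNV
calling. Spliced alignment is pluggable: alignments may come from an
external spliced aligner (SAM/BAM) or from the simulator's truth-alignment
tables, keyed by read id; a consensus molecule inherits the alignment of
its first member read.
"""

from __future__ import annotations

import collections
import json
import time
from dataclasses import dataclass, field, asdict
from typing import Mapping

import pandas as pd

from . import assigner, curator, quantifier, scanner, variants
from .io_formats import AlignmentRecord, GeneModel, RawRead


@dataclass
class PipelineConfig:
    adapter: scanner.AdapterConfig = field(default_factory=scanner.AdapterConfig)
    extend_pct: float = 0.10
    cb_max_ld: int = 2
    umi_max_ld: int = 2
    cluster_tol: int = 5
    min_genes: int = 300
    junction_tol: int = 10
    min_support: int = 2
    all_cell_frac: float = 0.01
    type_frac: float = 0.05


@dataclass
class PipelineResult:
    qc: scanner.QCReport
    rejections: dict[str, int]
    anchor: assigner.AnchorResult
    cells: list[str]                      # final (Cr4) cell list
    molecules: list[curator.Molecule]
    quant: quantifier.QuantResult
    variants: list[variants.Variant]
    manifest: dict


def run_pipeline(
    reads: list[RawRead],
    alignments: Mapping[str, AlignmentRecord],
    genes: list[GeneModel],
    reference: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage in memory; ``alignments`` maps read id -> spliced
    alignment of the read's insert (external aligner or truth-supplied)."""
    if config is None:
        config = PipelineConfig()
    manifest: dict = {"stages": {}, "parameters": {
        "extend_pct": config.extend_pct, "cb_max_ld": config.cb_max_ld,
        "umi_max_ld": config.umi_max_ld, "cluster_tol": config.cluster_tol,
        "min_genes": config.min_genes, "junction_tol": config.junction_tol,
        "min_support": config.min_support,
        "all_cell_frac": config.all_cell_frac, "type_frac": config.type_frac,
        "min_identity": config.adapter.min_identity,
        "min_insert_len": config.adapter.min_insert_len,
    }}

    def stage(name, n):
        manifest["stages"][name] = {"records": int(n), "t": round(time.time(), 2)}

    qc = scanner.nanoqc(reads)
    stage("nanoqc", qc.n_reads)

    tagged, rejections = scanner.scan_reads(reads, config.adapter)
    stage("scanner", len(tagged))
    if not tagged:
        raise RuntimeError("scanner: no reads passed adapter filtering")

    obs = pd.Series([t.raw_cb for t in tagged])
    curve, anchor = assigner.call_barcodes(
        obs, extend_pct=config.extend_pct, max_ld=config.cb_max_ld
    )
    read_cells, dropped = assigner.deconvolute(
        ((t.read_id, t.raw_cb) for t in tagged), anchor.merge_map, anchor.retained
    )
    stage("assigner", sum(len(v) for v in read_cells.values()))

    tagged_by_id = {t.read_id: t for t in tagged}
    all_molecules: list[curator.Molecule] = []
    mol_alignments: dict[str, AlignmentRecord] = {}
    assignments: list[tuple[str, str | None, dict[str, float]]] = []
    for cell in anchor.retained:
        read_ids = [r for r in read_cells.get(cell, []) if r in alignments]
        if not read_ids:
            continue
        cell_alns = [alignments[r] for r in read_ids]
        cell_reads = {
            r: RawRead(r, tagged_by_id[r].insert_seq, tagged_by_id[r].insert_quals)
            for r in read_ids
        }
        cell_umis = {r: tagged_by_id[r].raw_umi for r in read_ids}
        mols = curator.curate_cell(
            cell, cell_alns, cell_reads, cell_umis,
            tol=config.cluster_tol, umi_max_ld=config.umi_max_ld,
        )
        all_molecules.extend(mols)
        for mol in mols:
            # re-alignment: the molecule inherits its first member's alignment
            aln = alignments[mol.member_read_ids[0]]
            mol_alignments[f"{mol.cell}/{mol.umi}"] = AlignmentRecord(
                f"{mol.cell}/{mol.umi}", aln.chrom, aln.strand, list(aln.blocks)
            )
            gene = quantifier.assign_gene(aln, genes)
            iso = {}
            if gene is not None:
                gm = next(g for g in genes if g.gene_id == gene)
                iso = quantifier.assign_isoform(aln, gm, config.junction_tol)
            assignments.append((mol.cell, gene, iso))
    stage("curator", len(all_molecules))

    quant_all = quantifier.build_matrices(assignments, cells=anchor.retained)
    final_cells = assigner.filter_by_gene_count(
        anchor.retained, quant_all.per_cell_genes, config.min_genes
    )
    anchor.cr4 = len(final_cells)
    quant = quantifier.QuantResult(
        gene_matrix=quant_all.gene_matrix[final_cells],
        isoform_matrix=quant_all.isoform_matrix[final_cells],
        per_cell_genes={c: quant_all.per_cell_genes[c] for c in final_cells},
        unassigned=quant_all.unassigned,
    )
    stage("reporter", int(quant.gene_matrix.to_numpy().sum()))

    final_molecules = [m for m in all_molecules if m.cell in set(final_cells)]
    cols = variants.pileup(final_molecules, mol_alignments, reference)
    candidates = variants.call_candidates(
        cols, final_cells, min_support=config.min_support
    )
    stage("snv", len(candidates))

    result = PipelineResult(
        qc=qc,
        rejections=dict(rejections),
        anchor=anchor,
        cells=final_cells,
        molecules=final_molecules,
        quant=quant,
        variants=candidates,
        manifest=manifest,
    )
    return result


def filter_and_classify(
    result: PipelineResult,
    cell_types: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> list[variants.Variant]:
    """Apply the prevalence consensus filter and the germline/somatic
    classification to a pipeline result, given cell-type labels."""
    if config is None:
        config = PipelineConfig()
    kept = variants.consensus_filter(
        result.variants, cell_types,
        all_cell_frac=config.all_cell_frac, type_frac=config.type_frac,
    )
    variants.classify_germline_somatic(kept)
    return kept
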