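"""Synthetic-experiment generator.

Emulates a 10x-style nanopore full-length cDNA library: a known set of
cell barcodes with heavy-tailed supporting-read counts plus ambient noise
barcodes, PCR-duplicate UMI families, nanopore-style substitution/indel
errors, per-cell-type isoform mixtures with planted composition shifts,
and planted SNVs with per-cell-type cellular frequencies. Truth tables are
emitted alongside the reads so every pipeline stage can be checked without
an external aligner.

Three scale-matched generators are provided: the full read-level
experiment (`simulate_experiment`), a barcode-observation generator for
exercising the cell caller at realistic depth, and count-level generators
for the isoform-composition and mutation-expansion statistics.
"""

from __future__ import annotations

import collections
import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assigner import levenshtein
from .io_formats import AlignmentRecord, GeneModel, RawRead, TranscriptModel
from .scanner import R1_ADAPTER, TSO_ADAPTER, revcomp

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    seed: int = 0
    n_cell_types: int = 3
    cells_per_type: int = 10
    n_genes: int = 25
    max_isoforms: int = 3
    cb_len: int = 16
    umi_len: int = 12
    mol_per_cell_mean: float = 60.0
    mol_per_cell_dispersion: float = 10.0
    mol_per_cell_floor: int = 20     # every simulated cell stays detectable
    baseline_genes_per_cell: int = 12
    dup_mean: float = 3.0            # duplicates per molecule: 1 + Poisson(mean-1)
    barcode_sub: float = 0.0
    barcode_indel: float = 0.0
    body_sub: float = 0.0
    body_indel: float = 0.0
    ambient_barcodes: int = 40
    ambient_reads: int = 60
    n_dci_genes: int = 3
    dci_high: float = 0.8            # first-isoform share in the planted cell type
    n_snvs: int = 3
    snv_high_freq: float = 0.5       # carrier frequency in the planted cell type
    snv_low_freq: float = 0.05
    r1_adapter: str = R1_ADAPTER
    tso_adapter: str = TSO_ADAPTER
    polyt_len: int = 20
    strand_flip: float = 0.5
    exons_min: int = 3
    exons_max: int = 5
    exon_min: int = 150
    exon_max: int = 220
    intron_min: int = 120
    intron_max: int = 250
    spacer: int = 300
    min_cb_dist: int = 4             # planted CBs pairwise LD > this

    def __post_init__(self) -> None:
        for name in ("barcode_sub", "barcode_indel", "body_sub", "body_indel",
                     "strand_flip", "dci_high", "snv_high_freq", "snv_low_freq"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.n_cell_types * self.cells_per_type


@dataclass
class SimTruth:
    cbs: list[str]
    cell_types: dict[str, str]
    molecules: pd.DataFrame          # mol_id, cell, umi, gene, transcript, n_dups
    gene_matrix: pd.DataFrame
    isoform_matrix: pd.DataFrame
    variants: pd.DataFrame           # chrom, pos, ref, alt, cell, state (long)
    read_alignments: dict[str, AlignmentRecord]


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    reads: list[RawRead]
    truth: SimTruth


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def random_barcodes(
    n: int,
    length: int,
    rng: np.random.Generator,
    min_dist: int = 0,
    avoid: list[str] | None = None,
    avoid_dist: int = 0,
) -> list[str]:
    """Random barcodes, optionally pairwise LD > min_dist and LD > avoid_dist
    from every barcode in ``avoid``."""
    out: list[str] = []
    avoid = avoid or []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("cannot satisfy barcode distance constraints")
        cand = random_dna(length, rng)
        if min_dist and any(levenshtein(cand, b, k=min_dist) <= min_dist for b in out):
            continue
        if avoid_dist and any(
            levenshtein(cand, b, k=avoid_dist) <= avoid_dist for b in avoid
        ):
            continue
        out.append(cand)
    return out


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def corrupt(seq: str, rng: np.random.Generator, sub: float, indel: float) -> str:
    """Independent per-base substitution and single-base indel errors."""
    if sub == 0.0 and indel == 0.0:
        return seq
    out: list[str] = []
    for ch in seq:
        r = rng.random()
        if r < indel / 2:
            continue  # deletion
        if sub and ch in _BASE_INDEX and rng.random() < sub:
            ch = "ACGT"[(_BASE_INDEX[ch] + int(rng.integers(1, 4))) % 4]
        out.append(ch)
        if indel / 2 <= r < indel:
            out.append(random_dna(1, rng))  # insertion
    return "".join(out)


# ---------------------------------------------------------------------------
# toy reference
# ---------------------------------------------------------------------------

def build_toy_reference(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome with multi-exon genes whose isoforms share exons.

    Isoform 1 of each gene uses the full exon chain; each additional
    isoform skips one distinct internal exon, so full-length molecules
    carry isoform-diagnostic junctions while sharing terminal exons.
    """
    chrom = "chr1"
    parts: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []
    for g in range(config.n_genes):
        parts.append(random_dna(config.spacer, rng))
        cursor += config.spacer
        n_exons = int(rng.integers(config.exons_min, config.exons_max + 1))
        exons: list[tuple[int, int]] = []
        for _ in range(n_exons):
            elen = int(rng.integers(config.exon_min, config.exon_max + 1))
            exons.append((cursor, cursor + elen))
            parts.append(random_dna(elen, rng))
            cursor += elen
            ilen = int(rng.integers(config.intron_min, config.intron_max + 1))
            parts.append(random_dna(ilen, rng))
            cursor += ilen
        gene_id = f"G{g:03d}"
        n_iso = int(rng.integers(1, config.max_isoforms + 1))
        n_iso = min(n_iso, max(n_exons - 2, 1))
        txs = [TranscriptModel(f"{gene_id}.T1", list(exons))]
        skippable = list(range(1, n_exons - 1))
        rng.shuffle(skippable)
        for k in range(1, n_iso):
            skip = skippable[k - 1]
            txs.append(
                TranscriptModel(
                    f"{gene_id}.T{k + 1}",
                    [e for j, e in enumerate(exons) if j != skip],
                )
            )
        genes.append(
            GeneModel(gene_id, chrom, "+", (exons[0][0], exons[-1][1]), txs)
        )
    parts.append(random_dna(config.spacer, rng))
    genome = {"chr1": "".join(parts)}
    if len(genome["chr1"]) < genes[-1].span[1]:
        raise ValueError("genome too small for requested genes")
    return genome, genes


def _splice(genome: dict[str, str], chrom: str, exons) -> str:
    return "".join(genome[chrom][s:e] for s, e in exons)


# ---------------------------------------------------------------------------
# full read-level experiment
# ---------------------------------------------------------------------------

def simulate_experiment(config: SimConfig) -> SimResult:
    rng = np.random.default_rng(config.seed)
    genome, genes = build_toy_reference(config, rng)

    cbs = random_barcodes(config.n_cells, config.cb_len, rng,
                          min_dist=config.min_cb_dist)
    cell_types = {
        cb: f"type{j // config.cells_per_type}" for j, cb in enumerate(cbs)
    }
    type_names = [f"type{t}" for t in range(config.n_cell_types)]

    # per-gene expression weights (heavy-tailed) and per-type isoform mixtures
    weights = rng.lognormal(0.0, 1.0, config.n_genes)
    weights /= weights.sum()
    dci_genes = [g for g in range(min(config.n_dci_genes, config.n_genes))
                 if len(genes[g].transcripts) >= 2]
    mixtures: dict[tuple[int, str], np.ndarray] = {}
    for g, gene in enumerate(genes):
        k = len(gene.transcripts)
        base = rng.dirichlet(np.ones(k) * 2.0)
        for t, tname in enumerate(type_names):
            if g in dci_genes and k >= 2:
                hi, lo = config.dci_high, 1.0 - config.dci_high
                mix = np.full(k, lo / (k - 1))
                mix[0 if t == 0 else 1] = hi
                mix /= mix.sum()
                mixtures[(g, tname)] = mix
            else:
                mixtures[(g, tname)] = base

    # planted SNVs in the first exon (shared by all isoforms) of dedicated genes
    snv_genes = list(
        range(len(dci_genes), min(len(dci_genes) + config.n_snvs, config.n_genes))
    )
    snv_spec = []  # (gene idx, pos, ref, alt, enriched type)
    for j, g in enumerate(snv_genes):
        e0 = genes[g].transcripts[0].exons[0]
        pos = (e0[0] + e0[1]) // 2
        ref = genome["chr1"][pos]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        snv_spec.append((g, pos, ref, alt, type_names[j % config.n_cell_types]))
    carriers: dict[tuple[int, str], bool] = {}
    for (g, pos, ref, alt, etype) in snv_spec:
        for cb in cbs:
            freq = config.snv_high_freq if cell_types[cb] == etype else config.snv_low_freq
            carriers[(g, cb)] = bool(rng.random() < freq)

    # molecules
    mol_rows = []
    templates: dict[int, str] = {}
    mol_align: dict[int, AlignmentRecord] = {}
    mol_id = 0
    disp = config.mol_per_cell_dispersion
    p_nb = disp / (disp + config.mol_per_cell_mean)
    for cb in cbs:
        n_mol = max(int(rng.negative_binomial(disp, p_nb)), config.mol_per_cell_floor)
        cell_umis: set[str] = set()
        # broad baseline expression: the first molecules cover distinct genes
        # (housekeeping-like breadth), the rest follow the weighted model
        n_base = min(config.baseline_genes_per_cell, config.n_genes, n_mol)
        base_genes = rng.choice(config.n_genes, n_base, replace=False)
        for k in range(n_mol):
            if k < n_base:
                g = int(base_genes[k])
            else:
                g = int(rng.choice(config.n_genes, p=weights))
            gene = genes[g]
            mix = mixtures[(g, cell_types[cb])]
            tx = gene.transcripts[int(rng.choice(len(mix), p=mix))]
            while True:  # collision-free UMIs within a cell
                umi = random_dna(config.umi_len, rng)
                if all(levenshtein(umi, u, k=2) > 2 for u in cell_umis):
                    break
            cell_umis.add(umi)
            template = _splice(genome, gene.chrom, tx.exons)
            spec = next((s for s in snv_spec if s[0] == g), None)
            if spec is not None and carriers[(g, cb)]:
                _, pos, ref, alt, _ = spec
                offset = 0
                for s, e in tx.exons:
                    if s <= pos < e:
                        idx = offset + (pos - s)
                        template = template[:idx] + alt + template[idx + 1 :]
                        break
                    offset += e - s
            n_dups = 1 + int(rng.poisson(max(config.dup_mean - 1.0, 0.0)))
            mol_rows.append(
                {
                    "mol_id": mol_id,
                    "cell": cb,
                    "umi": umi,
                    "gene": gene.gene_id,
                    "transcript": tx.transcript_id,
                    "n_dups": n_dups,
                }
            )
            templates[mol_id] = template
            mol_align[mol_id] = AlignmentRecord(
                f"{cb}/{umi}", gene.chrom, "+", list(tx.exons)
            )
            mol_id += 1
    molecules = pd.DataFrame(
        mol_rows,
        columns=["mol_id", "cell", "umi", "gene", "transcript", "n_dups"],
    )

    # reads
    reads: list[RawRead] = []
    read_alignments: dict[str, AlignmentRecord] = {}

    def assemble(read_id: str, cb: str, umi: str, template: str) -> RawRead:
        cb_obs = corrupt(cb, rng, config.barcode_sub, config.barcode_indel)
        umi_obs = corrupt(umi, rng, config.barcode_sub, config.barcode_indel)
        body = corrupt(
            "T" * config.polyt_len + template + config.tso_adapter,
            rng, config.body_sub, config.body_indel,
        )
        adapter = corrupt(config.r1_adapter, rng, config.body_sub, config.body_indel)
        seq = adapter + cb_obs + umi_obs + body
        quals = rng.integers(20, 41, len(seq)).tolist()
        if rng.random() < config.strand_flip:
            seq = revcomp(seq)
            quals = quals[::-1]
        return RawRead(read_id, seq, quals)

    for row in molecules.itertuples(index=False):
        tmpl = templates[row.mol_id]
        aln = mol_align[row.mol_id]
        for d in range(row.n_dups):
            rid = f"r{row.mol_id}_{d}"
            reads.append(assemble(rid, row.cell, row.umi, tmpl))
            read_alignments[rid] = AlignmentRecord(rid, aln.chrom, "+", list(aln.blocks))

    # ambient reads from noise barcodes
    amb_cbs = random_barcodes(
        config.ambient_barcodes, config.cb_len, rng, avoid=cbs, avoid_dist=2
    ) if config.ambient_barcodes else []
    for a in range(config.ambient_reads):
        cb = amb_cbs[int(rng.integers(0, len(amb_cbs)))]
        g = int(rng.choice(config.n_genes, p=weights))
        tx = genes[g].transcripts[0]
        rid = f"amb{a}"
        reads.append(
            assemble(rid, cb, random_dna(config.umi_len, rng),
                     _splice(genome, genes[g].chrom, tx.exons))
        )
        read_alignments[rid] = AlignmentRecord(rid, genes[g].chrom, "+", list(tx.exons))

    # truth matrices
    gene_ids = [g.gene_id for g in genes]
    tx_ids = [tx.transcript_id for g in genes for tx in g.transcripts]
    gene_matrix = pd.DataFrame(0, index=gene_ids, columns=cbs, dtype=int)
    isoform_matrix = pd.DataFrame(0, index=tx_ids, columns=cbs, dtype=int)
    for row in molecules.itertuples(index=False):
        gene_matrix.loc[row.gene, row.cell] += 1
        isoform_matrix.loc[row.transcript, row.cell] += 1
    assert int(gene_matrix.to_numpy().sum()) == len(molecules)
    assert int(isoform_matrix.to_numpy().sum()) == len(molecules)

    # truth variant states; alt_molecules = total molecules carrying the
    # alternative allele (a variant is discoverable iff this is >= 2)
    var_rows = []
    for (g, pos, ref, alt, etype) in snv_spec:
        gid = genes[g].gene_id
        alt_molecules = sum(
            int(gene_matrix.loc[gid, cb]) for cb in cbs if carriers[(g, cb)]
        )
        for cb in cbs:
            n_gene_mols = int(gene_matrix.loc[gid, cb])
            if n_gene_mols == 0:
                state = "missing"
            elif carriers[(g, cb)]:
                state = "mutant"
            else:
                state = "wild-type"
            var_rows.append(
                {"chrom": "chr1", "pos": pos, "ref": ref, "alt": alt,
                 "cell": cb, "state": state, "enriched_type": etype,
                 "alt_molecules": alt_molecules}
            )
    variants = pd.DataFrame(
        var_rows,
        columns=["chrom", "pos", "ref", "alt", "cell", "state",
                 "enriched_type", "alt_molecules"],
    )

    truth = SimTruth(
        cbs=cbs,
        cell_types=cell_types,
        molecules=molecules,
        gene_matrix=gene_matrix,
        isoform_matrix=isoform_matrix,
        variants=variants,
        read_alignments=read_alignments,
    )
    return SimResult(config, genome, genes, reads, truth)


# ---------------------------------------------------------------------------
# barcode-observation generator (cell-caller scale)
# ---------------------------------------------------------------------------

def simulate_barcode_observations(
    rng: np.random.Generator,
    n_true: int = 500,
    n_ambient: int = 20000,
    cb_len: int = 16,
    depth_median: float = 1500.0,
    depth_sigma: float = 0.6,
    depth_min: int = 50,
    ambient_p: float = 0.6,
    ambient_max: int = 10,
    sub: float = 0.02,
    indel: float = 0.01,
) -> tuple[list[str], list[str], np.ndarray]:
    """Observed (error-corrupted) CB strings at realistic depth.

    True CBs (pairwise LD > 4) have log-normal heavy-tailed read depths;
    ambient barcodes carry small geometric read counts. Returns
    (observations, true CBs, true depths).
    """
    true_cbs = random_barcodes(n_true, cb_len, rng, min_dist=4)
    depths = np.maximum(
        np.round(rng.lognormal(math.log(depth_median), depth_sigma, n_true)),
        depth_min,
    ).astype(int)
    amb_cbs = [random_dna(cb_len, rng) for _ in range(n_ambient)]
    amb_counts = np.minimum(rng.geometric(ambient_p, n_ambient), ambient_max)

    sources: list[str] = []
    for cb, d in zip(true_cbs, depths):
        sources.extend([cb] * int(d))
    for cb, d in zip(amb_cbs, amb_counts):
        sources.extend([cb] * int(d))

    n = len(sources)
    mat = np.frombuffer("".join(sources).encode(), dtype=np.uint8).reshape(n, cb_len)
    mat = mat.copy()
    # vectorised substitutions
    if sub > 0:
        base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        idx = np.searchsorted(np.sort(base_codes), mat)  # ACGT are sorted
        hit = rng.random((n, cb_len)) < sub
        shift = rng.integers(1, 4, (n, cb_len))
        idx = np.where(hit, (idx + shift) % 4, idx)
        mat = np.sort(base_codes)[idx]
    observations = [bytes(row).decode() for row in mat]
    # indels handled per affected read (rare); the extracted barcode stays
    # cb_len long, padded with downstream (random) bases after a deletion
    if indel > 0:
        n_events = rng.binomial(cb_len, indel, n)
        for j in np.flatnonzero(n_events > 0):
            s = observations[j]
            for _ in range(int(n_events[j])):
                pos = int(rng.integers(0, len(s)))
                if rng.random() < 0.5:
                    s = s[:pos] + s[pos + 1 :]
                else:
                    s = s[:pos] + random_dna(1, rng) + s[pos:]
            if len(s) < cb_len:
                s = s + random_dna(cb_len - len(s), rng)
            observations[j] = s[:cb_len]
    return observations, true_cbs, depths


# ---------------------------------------------------------------------------
# count-level generators for the statistics
# ---------------------------------------------------------------------------

def simulate_isoform_counts(
    rng: np.random.Generator,
    n_genes: int = 500,
    cells_per_group: int = 200,
    mol_per_cell: float = 5.0,
    shift: float = 0.0,
    base_mix: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Two-isoform genes across two cell groups.

    Group A expresses isoform 1 of every gene with probability
    ``base_mix + shift/2`` and group B with ``base_mix - shift/2``
    (shift = 0 is the null). Molecules per gene per cell are Poisson.
    Returns (isoform x cell matrix, isoform -> gene, cell -> group).
    """
    cells = [f"A{j}" for j in range(cells_per_group)] + [
        f"B{j}" for j in range(cells_per_group)
    ]
    labels = {c: ("A" if c.startswith("A") else "B") for c in cells}
    p_a = min(max(base_mix + shift / 2.0, 0.0), 1.0)
    p_b = min(max(base_mix - shift / 2.0, 0.0), 1.0)
    n = rng.poisson(mol_per_cell, (n_genes, 2 * cells_per_group))
    p = np.concatenate(
        [np.full(cells_per_group, p_a), np.full(cells_per_group, p_b)]
    )
    iso1 = rng.binomial(n, p[None, :])
    iso2 = n - iso1
    rows = np.empty((2 * n_genes, 2 * cells_per_group), dtype=float)
    rows[0::2] = iso1
    rows[1::2] = iso2
    index = [
        f"G{g:04d}.T{k}" for g in range(n_genes) for k in (1, 2)
    ]
    matrix = pd.DataFrame(rows, index=index, columns=cells)
    iso_gene = {t: t.split(".")[0] for t in index}
    return matrix, iso_gene, labels


def simulate_variant_counts(
    rng: np.random.Generator,
    n_error_loci: int = 500,
    n_planted: int = 20,
    cells_per_type: int = 200,
    n_types: int = 3,
    coverage_mean: float = 2.5,
    dup_mean: float = 2.5,
    read_error: float = 0.01,
    planted_high: float = 0.30,
    planted_low: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], np.ndarray]:
    """Locus x cell consensus depth/alt-count tables.

    Error loci carry no cellular structure: each covering molecule's
    consensus base is the majority over its duplicate reads, each read
    wrong with probability ``read_error`` (uniform over the three
    alternative bases). Planted loci have carrier cells (frequency
    ``planted_high`` in type0, ``planted_low`` elsewhere) whose molecules
    all carry the alternative allele. Returns (depth, alt, cell -> type,
    boolean mask of planted rows).
    """
    n_cells = cells_per_type * n_types
    cells = [f"c{j:04d}" for j in range(n_cells)]
    types = {c: f"type{j // cells_per_type}" for j, c in enumerate(cells)}
    n_loci = n_error_loci + n_planted
    depth = rng.poisson(coverage_mean, (n_loci, n_cells))

    alt = np.zeros_like(depth)
    # error loci: each molecule's consensus base is the strict majority of
    # its duplicate reads; one simulation round per molecule layer
    p_alt_read = read_error / 3.0
    err_depth = depth[:n_error_loci]
    err_alt = alt[:n_error_loci].ravel()
    max_depth = int(err_depth.max()) if n_error_loci else 0
    for m in range(1, max_depth + 1):
        flat = np.flatnonzero((err_depth >= m).ravel())
        if flat.size == 0:
            continue
        k = 1 + rng.poisson(max(dup_mean - 1.0, 0.0), flat.size)
        x = rng.binomial(k, p_alt_read)
        err_alt[flat] += (2 * x > k).astype(int)
    alt[:n_error_loci] = err_alt.reshape(err_depth.shape)

    # planted loci: carriers' molecules all carry the alternative allele
    planted = np.zeros(n_loci, dtype=bool)
    planted[n_error_loci:] = True
    type_arr = np.array([types[c] for c in cells])
    for r in range(n_error_loci, n_loci):
        freq = np.where(type_arr == "type0", planted_high, planted_low)
        carrier = rng.random(n_cells) < freq
        alt[r] = np.where(carrier, depth[r], 0)

    depth_df = pd.DataFrame(depth, index=range(n_loci), columns=cells)
    alt_df = pd.DataFrame(alt, index=range(n_loci), columns=cells)
    return depth_df, alt_df, types, planted
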