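"""Seeded benchmark computations over synthetic data.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stages, and returns summary metrics. Reference ("oracle")
computations used for agreement checks are deliberately written as plain
exhaustive implementations, independent of the package code paths they
validate.
"""

from __future__ import annotations

import itertools
import math
import statistics
import warnings

import edlib
import numpy as np
import pandas as pd
from scipy import stats as sps

from . import assigner, curator, pipeline, simulator, stats, variants
from .simulator import SimConfig, corrupt, random_dna


# ---------------------------------------------------------------------------
# barcode calling at depth
# ---------------------------------------------------------------------------

def barcode_recovery(seed: int) -> dict:
    """500 planted CBs (heavy-tailed depth, pairwise LD > 4) + 20,000
    ambient barcodes, barcode errors 2% substitution + 1% indel."""
    rng = np.random.default_rng(seed)
    obs, true_cbs, _ = simulator.simulate_barcode_observations(rng)
    _, anchor = assigner.call_barcodes(obs)
    called = set(anchor.retained)
    tp = len(called & set(true_cbs))
    return {
        "recovery_pct": 100.0 * tp / len(true_cbs),
        "false_positive_pct": 100.0 * (len(called) - tp) / max(len(called), 1),
        "cr": anchor.cr,
        "cr3": anchor.cr3,
        "n_true": len(true_cbs),
        "n_observations": len(obs),
    }


# ---------------------------------------------------------------------------
# knee detection vs exhaustive window evaluation
# ---------------------------------------------------------------------------

def _reference_anchor(counts) -> int:
    """Plain per-rank/window evaluation of the median-derivative statistic."""
    windows: dict[int, list[float]] = {}
    for i in range(1, len(counts)):
        d = (math.log10(counts[i]) - math.log10(counts[i - 1])) / (
            math.log10(i + 1) - math.log10(i)
        )
        w = math.floor(math.log10(i) / 0.001)
        windows.setdefault(w, []).append(d)
    med = {w: statistics.median(v) for w, v in windows.items()}
    w_star = max(sorted(med), key=lambda w: abs(med[w]))
    return max(int(round(10 ** (0.001 * w_star))), 1)


def knee_oracle(seed: int, n_random: int = 10) -> dict:
    """Exact agreement of the knee finder with exhaustive evaluation on a
    battery of curves: two-plateau, random knee curves, and a realistic
    barcode-observation curve."""
    rng = np.random.default_rng(seed)
    curves = [np.array([1000] * 100 + [10] * 900)]
    for _ in range(n_random):
        n_true = int(rng.integers(50, 500))
        top = np.sort(rng.integers(300, 5000, n_true))[::-1]
        tail = np.sort(rng.integers(1, 20, int(rng.integers(2000, 8000))))[::-1]
        curves.append(np.concatenate([top, tail]))
    obs, _, _ = simulator.simulate_barcode_observations(
        rng, n_true=200, n_ambient=3000, sub=0.01, indel=0.005
    )
    curves.append(assigner.count_barcodes(obs).counts)
    agree = sum(
        assigner.crude_anchor(c) == _reference_anchor(c) for c in curves
    )
    return {"agreement_pct": 100.0 * agree / len(curves), "n_curves": len(curves)}


# ---------------------------------------------------------------------------
# UMI curation vs exhaustive single-linkage
# ---------------------------------------------------------------------------

def _single_linkage(umis, max_ld=2):
    parent = list(range(len(umis)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(len(umis)), 2):
        d = edlib.align(umis[i], umis[j], task="distance", k=max_ld)["editDistance"]
        if d != -1:
            parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(umis)):
        groups.setdefault(find(i), []).append(i)
    return {frozenset(v) for v in groups.values()}


def umi_oracle(seed: int, n_clusters: int = 100, reads_per_cluster: int = 200) -> dict:
    """Agreement of the directional UMI merge with exhaustive pairwise-LD
    single-linkage on random read clusters."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_clusters):
        base = [random_dna(12, rng) for _ in range(int(rng.integers(30, 80)))]
        umis = [base[int(rng.integers(0, len(base)))] for _ in range(reads_per_cluster)]
        mine = {frozenset(v) for v in curator.curate_umis(umis).values()}
        agree += mine == _single_linkage(umis)
    return {"agreement_pct": 100.0 * agree / n_clusters, "n_clusters": n_clusters}


# ---------------------------------------------------------------------------
# consensus recovery
# ---------------------------------------------------------------------------

def consensus_recovery(
    seed: int, trials: int = 1000, n_dups: int = 5,
    template_len: int = 300, sub: float = 0.02,
) -> dict:
    """Exact template recovery from duplicate reads with substitutions."""
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(trials):
        template = random_dna(template_len, rng)
        seqs = [corrupt(template, rng, sub, 0.0) for _ in range(n_dups)]
        quals = [rng.integers(20, 41, len(s)).tolist() for s in seqs]
        cons, _ = curator.build_consensus(seqs, quals)
        wins += cons == template
    return {"recovery_pct": 100.0 * wins / trials, "n_trials": trials}


# ---------------------------------------------------------------------------
# chi-square / BH agreement
# ---------------------------------------------------------------------------

def _bh_reference(pvalues):
    """Textbook step-up, computed rank by rank in pure python."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda j: pvalues[j])
    adjusted = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        j = order[rank - 1]
        running = min(running, pvalues[j] * n / rank)
        adjusted[j] = running
    return adjusted


def stats_oracles(seed: int, n_tables: int = 50) -> dict:
    """Relative agreement of the chi-square and BH implementations with
    independent references on random tables, plus the hand-derivable
    [[50,50],[90,10]] statistic."""
    rng = np.random.default_rng(seed)
    max_chi_err = 0.0
    for _ in range(n_tables):
        r, c = rng.integers(2, 5, 2)
        table = rng.integers(1, 300, (int(r), int(c)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mine, mine_p, _ = stats.chi_square(table)
        ref, ref_p, _, _ = sps.chi2_contingency(table, correction=False)
        max_chi_err = max(
            max_chi_err,
            abs(mine - ref) / max(abs(ref), 1e-300),
            abs(mine_p - ref_p) / max(abs(ref_p), 1e-300),
        )
    max_bh_err = 0.0
    for _ in range(n_tables):
        p = rng.random(int(rng.integers(1, 150)))
        mine = stats.bh_adjust(p)
        ref = _bh_reference(list(p))
        max_bh_err = max(max_bh_err, float(np.max(np.abs(mine - ref))))
    example, _, _ = stats.chi_square([[50, 50], [90, 10]])
    return {
        "chisq_example_statistic": example,
        "chisq_max_rel_err": max_chi_err,
        "bh_max_abs_err": max_bh_err,
        "n_tables": n_tables,
    }


# ---------------------------------------------------------------------------
# DCI operating characteristics
# ---------------------------------------------------------------------------

def dci_operating_characteristics(
    seed: int, n_null_seeds: int = 20, n_null_genes: int = 500,
    n_power_seeds: int = 3, n_power_genes: int = 200, shift: float = 0.30,
) -> dict:
    """Type-I control on null replicates and power on a planted 30-point
    isoform-composition shift (200 cells per group, ~5 molecules/cell)."""
    ss = np.random.SeedSequence(seed)
    null_frac = []
    for child in ss.spawn(n_null_seeds):
        rng = np.random.default_rng(child)
        m, iso_gene, labels = simulator.simulate_isoform_counts(
            rng, n_genes=n_null_genes, shift=0.0
        )
        res = stats.dci_test(m, iso_gene, stats.GroupDesign(labels, "A", "B"))
        null_frac.append(sum(r.is_dci for r in res) / max(len(res), 1))
    detected = total = 0
    for child in ss.spawn(n_power_seeds):
        rng = np.random.default_rng(child)
        m, iso_gene, labels = simulator.simulate_isoform_counts(
            rng, n_genes=n_power_genes, shift=shift
        )
        res = stats.dci_test(m, iso_gene, stats.GroupDesign(labels, "A", "B"))
        detected += sum(r.is_dci for r in res)
        total += len(res)
    return {
        "null_discovery_frac": float(np.mean(null_frac)),
        "power_pct": 100.0 * detected / max(total, 1),
        "n_null_tests": n_null_seeds * n_null_genes,
        "n_power_tests": total,
    }


# ---------------------------------------------------------------------------
# deMut recovery and error removal
# ---------------------------------------------------------------------------

def demut_recovery(seed: int) -> dict:
    """Planted variants at 30% cellular frequency in one cell type versus
    5% elsewhere must be detected; unstructured errors (1% per-base read
    errors surviving duplicate-consensus) must be removed by the 1%/5%
    prevalence filter."""
    rng = np.random.default_rng(seed)
    depth, alt, types, planted = simulator.simulate_variant_counts(rng)
    candidates = variants.variants_from_counts(depth, alt)
    kept = variants.consensus_filter(candidates, types)
    err_total = int((~planted).sum())
    err_kept = sum(1 for v in kept if not planted[v.pos])
    planted_kept = [v for v in kept if planted[v.pos]]
    states = pd.DataFrame(
        {c: [v.states[c] for v in planted_kept] for c in depth.columns},
        index=[v.pos for v in planted_kept],
    )
    detected = 0
    if len(planted_kept):
        res = stats.demut_test(states, stats.GroupDesign(types, "type0", "rest"))
        detected = sum(r.is_demut for r in res)
    return {
        "error_removed_pct": 100.0 * (1 - err_kept / max(err_total, 1)),
        "planted_detected_pct": 100.0 * detected / max(int(planted.sum()), 1),
        "n_error_loci": err_total,
        "n_planted": int(planted.sum()),
    }


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def _run(config: SimConfig):
    sim = simulator.simulate_experiment(config)
    result = pipeline.run_pipeline(
        sim.reads, sim.truth.read_alignments, sim.genes, sim.genome,
        pipeline.PipelineConfig(min_genes=10),
    )
    return sim, result


def end_to_end_noiseless(seed: int) -> dict:
    """Noiseless simulation must reproduce truth exactly: cells, molecule
    counts, gene/isoform matrices, and per-cell variant carrier states."""
    sim, result = _run(SimConfig(seed=seed))
    cells_ok = set(result.cells) == set(sim.truth.cbs)
    mols_ok = len(result.molecules) == len(sim.truth.molecules)
    gm = result.quant.gene_matrix.reindex(
        index=sim.truth.gene_matrix.index, columns=sim.truth.cbs, fill_value=0
    )
    genes_ok = gm.astype(int).equals(sim.truth.gene_matrix)
    im = result.quant.isoform_matrix.reindex(
        index=sim.truth.isoform_matrix.index, columns=sim.truth.cbs, fill_value=0.0
    )
    iso_ok = bool(np.allclose(im.to_numpy(), sim.truth.isoform_matrix.to_numpy()))
    called = {(v.chrom, v.pos, v.ref, v.alt): v for v in result.variants}
    var_ok = True
    for key, grp in sim.truth.variants.groupby(["chrom", "pos", "ref", "alt"]):
        v = called.get(key)
        if int(grp.iloc[0].alt_molecules) < 2:
            # below the two-consensus-molecule support rule: must not call
            var_ok &= v is None
            continue
        if v is None:
            var_ok = False
            continue
        for row in grp.itertuples():
            var_ok &= v.states.get(row.cell) == row.state
    return {
        "exact": float(cells_ok and mols_ok and genes_ok and iso_ok and var_ok),
        "cells_exact": float(cells_ok),
        "molecules_exact": float(mols_ok),
        "matrices_exact": float(genes_ok and iso_ok),
        "variants_exact": float(var_ok),
        "n_reads": len(sim.reads),
    }


def end_to_end_noisy(seed: int) -> dict:
    """Per-cell gene counts under nanopore-like errors must rank-correlate
    with truth (Spearman over matched gene x cell entries)."""
    sim, result = _run(
        SimConfig(seed=seed, barcode_sub=0.01, barcode_indel=0.005,
                  body_sub=0.02, body_indel=0.01)
    )
    common = [c for c in sim.truth.cbs if c in result.quant.gene_matrix.columns]
    gm = result.quant.gene_matrix.reindex(
        index=sim.truth.gene_matrix.index, fill_value=0
    )[common]
    rho = sps.spearmanr(
        gm.to_numpy().ravel(), sim.truth.gene_matrix[common].to_numpy().ravel()
    ).statistic
    return {
        "gene_spearman": float(rho),
        "cells_recovered_pct": 100.0 * len(common) / len(sim.truth.cbs),
        "false_cells": len(set(result.cells) - set(sim.truth.cbs)),
        "n_entries": gm.size,
    }
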