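"""Differential isoform-combination (DCI) and differentially expanded
mutation (deMut) tests.

Both compare two cell groups with Pearson chi-square tests on aggregated
counts and Benjamini-Hochberg correction across tested features. A DCI
gene requires BH-adjusted p < 0.05 and at least one isoform whose cellular
prevalence differs between groups by >= 10 percentage points; a deMut
requires BH-adjusted p < 0.05 and a cellular-frequency difference > 0.1
(covered cells only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupDesign:
    """Cell -> group labels plus the two groups under comparison.

    ``group_b`` may be the literal string "rest" to pool all other labels.
    """

    labels: Mapping[str, str]
    group_a: str
    group_b: str = "rest"

    def cells(self, columns: Sequence[str]) -> tuple[list[str], list[str]]:
        a = [c for c in columns if self.labels.get(c) == self.group_a]
        if self.group_b == "rest":
            b = [c for c in columns if c in self.labels
                 and self.labels[c] != self.group_a]
        else:
            b = [c for c in columns if self.labels.get(c) == self.group_b]
        if not a or not b:
            raise ValueError(
                f"empty comparison group ({self.group_a!r} vs {self.group_b!r})"
            )
        return a, b


@dataclass
class DCIResult:
    gene: str
    table: pd.DataFrame              # isoforms x 2 aggregated counts
    statistic: float
    pvalue: float
    adjusted_p: float
    prevalence_a: dict[str, float]
    prevalence_b: dict[str, float]
    prevalence_diff: dict[str, float]
    mdt_a: str
    mdt_b: str
    is_dci: bool


@dataclass
class DeMutResult:
    locus: str
    table: np.ndarray                # 2x2: (mutant, wild-type) x (A, B)
    statistic: float
    pvalue: float
    adjusted_p: float
    freq_a: float
    freq_b: float
    freq_diff: float
    is_demut: bool


def chi_square(table) -> tuple[float, float, int]:
    """Pearson chi-square of independence, no continuity correction.

    Zero-margin rows/columns are dropped; a table degenerating below 2x2
    yields statistic 0, p = 1, df = 0.
    """
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0):
        raise ValueError("negative counts")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0] if obs.size else obs
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        return 0.0, 1.0, 0
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    if np.any(expected < 5):
        warnings.warn("expected cell count < 5; chi-square approximation is weak",
                      stacklevel=2)
    return stat, p, df


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(n)
    out[order] = ranked
    return out


def _prevalence(block: pd.DataFrame) -> tuple[dict[str, float], int]:
    """Per-isoform cellular prevalence within one group: cells with >= 1
    molecule of the isoform over cells with >= 1 molecule of the gene."""
    expressing = (block.sum(axis=0) > 0)
    n_expr = int(expressing.sum())
    if n_expr == 0:
        return {t: 0.0 for t in block.index}, 0
    prev = ((block.loc[:, expressing] > 0).sum(axis=1) / n_expr).to_dict()
    return prev, n_expr


def dci_test(
    isoform_matrix: pd.DataFrame,
    isoform_gene: Mapping[str, str],
    design: GroupDesign,
    expr_frac: float = 0.05,
    prev_diff: float = 0.10,
    alpha: float = 0.05,
) -> list[DCIResult]:
    """Per-gene test of differential isoform combination between groups.

    Genes detected in < expr_frac of cells in BOTH groups are skipped, as
    are genes with fewer than two isoforms with nonzero aggregate counts.
    The chi-square runs on the isoform x group aggregated molecule counts;
    BH correction spans all tested genes.
    """
    cells_a, cells_b = design.cells(isoform_matrix.columns)
    genes = pd.Series(
        [isoform_gene[t] for t in isoform_matrix.index], index=isoform_matrix.index
    )
    results: list[DCIResult] = []
    for gene, iso_idx in genes.groupby(genes).groups.items():
        if len(iso_idx) < 2:
            continue  # single-isoform gene
        block_a = isoform_matrix.loc[iso_idx, cells_a]
        block_b = isoform_matrix.loc[iso_idx, cells_b]
        det_a = float((block_a.sum(axis=0) > 0).mean())
        det_b = float((block_b.sum(axis=0) > 0).mean())
        if det_a < expr_frac and det_b < expr_frac:
            continue  # sporadically expressed
        agg = pd.DataFrame(
            {"A": block_a.sum(axis=1), "B": block_b.sum(axis=1)}
        )
        if int((agg.sum(axis=1) > 0).sum()) < 2:
            continue  # fewer than two isoforms observed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p, _ = chi_square(agg.to_numpy())
        prev_a, _ = _prevalence(block_a)
        prev_b, _ = _prevalence(block_b)
        diff = {t: prev_a[t] - prev_b[t] for t in prev_a}
        mdt_a = agg["A"].sort_index().idxmax()
        mdt_b = agg["B"].sort_index().idxmax()
        results.append(
            DCIResult(gene, agg, stat, p, np.nan, prev_a, prev_b, diff,
                      mdt_a, mdt_b, False)
        )
    if results:
        adj = bh_adjust([r.pvalue for r in results])
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
            r.is_dci = bool(
                q < alpha and max(abs(d) for d in r.prevalence_diff.values()) >= prev_diff
            )
    return results


def demut_test(
    states: pd.DataFrame,
    design: GroupDesign,
    type_frac: float = 0.05,
    freq_diff: float = 0.10,
    alpha: float = 0.05,
) -> list[DeMutResult]:
    """Per-locus test of differential mutation expansion between groups.

    ``states`` is a locus x cell table with entries 'mutant', 'wild-type'
    or 'missing'. Covered (non-missing) cells only. Loci with mutant
    fraction < type_frac in every compared group are skipped. The 2x2
    chi-square runs on (mutant, wild-type) x (group A, group B).
    """
    cells_a, cells_b = design.cells(states.columns)
    results: list[DeMutResult] = []
    for locus, row in states.iterrows():
        ra, rb = row[cells_a], row[cells_b]
        mut_a = int((ra == "mutant").sum())
        cov_a = int((ra != "missing").sum())
        mut_b = int((rb == "mutant").sum())
        cov_b = int((rb != "missing").sum())
        if cov_a == 0 or cov_b == 0:
            continue
        fa, fb = mut_a / cov_a, mut_b / cov_b
        if fa < type_frac and fb < type_frac:
            continue
        table = np.array([[mut_a, mut_b], [cov_a - mut_a, cov_b - mut_b]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p, _ = chi_square(table)
        results.append(
            DeMutResult(str(locus), table, stat, p, np.nan, fa, fb, fa - fb, False)
        )
    if results:
        adj = bh_adjust([r.pvalue for r in results])
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
            r.is_demut = bool(q < alpha and abs(r.freq_diff) > freq_diff)
    return results


def one_vs_rest(
    labels: Mapping[str, str],
    test: Callable[[GroupDesign], list],
) -> dict[str, list]:
    """Run ``test`` once per group against the pooled rest."""
    groups = sorted(set(labels.values()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out: dict[str, list] = {}
    for g in groups:
        if sum(1 for v in labels.values() if v == g) == 1:
            warnings.warn(f"group {g!r} has a single cell", stacklevel=2)
        out[g] = test(GroupDesign(labels, g, "rest"))
    return out
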