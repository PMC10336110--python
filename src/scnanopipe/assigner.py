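"""Whitelist-free cell-barcode calling and read deconvolution.

The barcode caller proceeds in four steps over the barcode rank curve
(CBs ordered by descending supporting-read count):

1. crude anchor -- the rank at which the log-log curve drops most steeply,
   found by median-smoothing per-rank discrete derivatives within 0.001-wide
   windows of log10(rank);
2. extension of the anchor by an empirical percentage (default 10%) to
   rescue true cells with few reads;
3. one-directional merging of barcodes within 2 Levenshtein distances into
   the barcode with more supporting reads;
4. removal of cells covering fewer than a minimum number of genes
   (default 300), applied downstream once genes have been counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd


@dataclass
class BarcodeRankCurve:
    """(CB, supporting reads) ordered by descending count; rank starts at 1."""

    barcodes: list[str]
    counts: np.ndarray  # int, non-increasing

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


@dataclass
class AnchorResult:
    cr: int
    cr2: int
    cr3: int
    cr4: int | None
    merge_map: dict[str, str]          # raw CB -> absorbing CB (over top-Cr2)
    retained: list[str]                # Cr3 list, descending merged count
    merged_counts: dict[str, int]

    def __post_init__(self) -> None:
        assert self.cr <= self.cr2 and self.cr3 <= self.cr2
        if self.cr4 is not None:
            assert self.cr4 <= self.cr3


def count_barcodes(observations: Iterable[str] | pd.Series) -> BarcodeRankCurve:
    """Exact supporting-read counts per CB; ties broken lexicographically."""
    s = pd.Series(list(observations) if not isinstance(observations, pd.Series)
                  else observations, dtype=str)
    if len(s) == 0:
        raise ValueError("no barcode observations")
    counts = s.value_counts()
    df = counts.rename_axis("cb").reset_index(name="n")
    df = df.sort_values(["n", "cb"], ascending=[False, True], kind="mergesort")
    return BarcodeRankCurve(df["cb"].tolist(), df["n"].to_numpy(dtype=np.int64))


def window_medians(counts: np.ndarray) -> dict[int, float]:
    """Median of per-rank log-log derivatives within each 0.001-wide window
    of log10(rank). Derivative at rank i (1-based) uses ranks i and i+1."""
    x = np.asarray(counts, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 ranks")
    i = np.arange(1, n)  # 1-based ranks 1..n-1 carry a derivative
    d = (np.log10(x[1:]) - np.log10(x[:-1])) / (np.log10(i + 1) - np.log10(i))
    w = np.floor(np.log10(i) / 0.001).astype(np.int64)
    out: dict[int, float] = {}
    order = np.argsort(w, kind="mergesort")
    w_sorted, d_sorted = w[order], d[order]
    boundaries = np.flatnonzero(np.diff(w_sorted)) + 1
    for chunk_w, chunk_d in zip(
        np.split(w_sorted, boundaries), np.split(d_sorted, boundaries)
    ):
        out[int(chunk_w[0])] = float(np.median(chunk_d))
    return out


def crude_anchor(curve: BarcodeRankCurve | np.ndarray, literal: bool = False) -> int:
    """Rank of the crude anchoring point (Cr).

    By default the window with the steepest descent (maximal |median
    derivative|) is selected; ``literal=True`` instead takes the literal
    argmax of the (non-positive) median derivative.
    """
    counts = curve.counts if isinstance(curve, BarcodeRankCurve) else np.asarray(curve)
    if len(np.unique(counts)) < 2:
        raise ValueError("no knee: all supporting-read counts are equal")
    med = window_medians(counts)
    if literal:
        best = max(med.items(), key=lambda kv: (kv[1], -kv[0]))
    else:
        best = max(med.items(), key=lambda kv: (abs(kv[1]), -kv[0]))
    if not literal and best[1] == 0:
        raise ValueError("no knee: all window derivatives are zero")
    w_star = best[0]
    cr = int(round(10 ** (0.001 * w_star)))
    return max(cr, 1)


def extend_anchor(cr: int, n: int, pct: float = 0.10) -> int:
    """Cr2 = ceil(Cr * (1 + pct)), capped at the curve length ``n``."""
    if cr < 1:
        raise ValueError("Cr must be >= 1")
    return min(math.ceil(cr * (1.0 + pct)), n)


def levenshtein(a: str, b: str, k: int | None = None) -> int:
    """Edit distance via edlib; with ``k``, returns k+1 when distance > k."""
    res = edlib.align(a, b, task="distance", k=-1 if k is None else k)
    d = res["editDistance"]
    return (k + 1) if d == -1 else d


def merge_barcodes_ld(
    barcodes: Sequence[str],
    counts: Sequence[int],
    max_ld: int = 2,
) -> tuple[dict[str, str], list[str], dict[str, int]]:
    """One-directional merge of CBs within ``max_ld`` Levenshtein distance.

    Barcodes are processed in descending supporting-read order (ties
    lexicographic); each is absorbed by the highest-count already-retained
    barcode within distance <= max_ld, else retained itself. Returns
    (merge map, retained list, merged counts). Counts are conserved.
    """
    order = sorted(range(len(barcodes)), key=lambda j: (-counts[j], barcodes[j]))
    retained: list[str] = []        # kept in processing order = descending count
    merge_map: dict[str, str] = {}
    merged_counts: dict[str, int] = {}
    for j in order:
        cb, n = barcodes[j], int(counts[j])
        absorber = None
        for cand in retained:  # descending original count, ties lexicographic
            if levenshtein(cb, cand, k=max_ld) <= max_ld:
                absorber = cand
                break
        if absorber is None:
            retained.append(cb)
            merge_map[cb] = cb
            merged_counts[cb] = n
        else:
            merge_map[cb] = absorber
            merged_counts[absorber] += n
    retained_sorted = sorted(retained, key=lambda c: (-merged_counts[c], c))
    return merge_map, retained_sorted, merged_counts


def filter_by_gene_count(
    cells: Sequence[str], gene_counts: Mapping[str, int], min_genes: int = 300
) -> list[str]:
    """Cr4: retain cells covering at least ``min_genes`` distinct genes."""
    return [c for c in cells if gene_counts.get(c, 0) >= min_genes]


def call_barcodes(
    observations: Iterable[str] | pd.Series,
    extend_pct: float = 0.10,
    max_ld: int = 2,
    literal_anchor: bool = False,
) -> tuple[BarcodeRankCurve, AnchorResult]:
    """Steps 1-3 of the barcode caller (the gene-count filter runs after
    quantification). Returns the rank curve and an AnchorResult with cr4=None."""
    curve = count_barcodes(observations)
    cr = crude_anchor(curve, literal=literal_anchor)
    cr2 = extend_anchor(cr, len(curve), extend_pct)
    merge_map, retained, merged_counts = merge_barcodes_ld(
        curve.barcodes[:cr2], curve.counts[:cr2], max_ld=max_ld
    )
    result = AnchorResult(
        cr=cr, cr2=cr2, cr3=len(retained), cr4=None,
        merge_map=merge_map, retained=retained, merged_counts=merged_counts,
    )
    return curve, result


def deconvolute(
    read_cbs: Iterable[tuple[str, str]],
    merge_map: Mapping[str, str],
    final_cbs: Iterable[str],
) -> tuple[dict[str, list[str]], int]:
    """Assign reads (read_id, raw CB) to final cells via the merge map.

    Reads whose raw CB is absent from the merge map, or maps to a CB not in
    the final list, are dropped. Returns (cell -> read ids, dropped count).
    """
    final = set(final_cbs)
    cells: dict[str, list[str]] = {cb: [] for cb in final}
    dropped = 0
    for read_id, raw_cb in read_cbs:
        target = merge_map.get(raw_cb)
        if target is None or target not in final:
            dropped += 1
        else:
            cells[target].append(read_id)
    return cells, dropped
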