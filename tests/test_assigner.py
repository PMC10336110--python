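import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scnanopipe import assigner


# ---------------------------------------------------------------------------
# count_barcodes
# ---------------------------------------------------------------------------

def test_count_barcodes_orders_by_count_then_lexicographic():
    obs = ["AAAC"] * 3 + ["GGGT"] + ["CCCC"] * 2 + ["AAAA"] * 2
    curve = assigner.count_barcodes(obs)
    assert curve.barcodes == ["AAAC", "AAAA", "CCCC", "GGGT"]
    assert curve.counts.tolist() == [3, 2, 2, 1]
    assert curve.total_reads == len(obs)


def test_count_barcodes_empty_errors():
    with pytest.raises(ValueError):
        assigner.count_barcodes([])


def test_count_barcodes_mass_conserved(rng):
    cbs = [f"CB{j:04d}" for j in range(100)]
    obs = list(rng.choice(cbs, 5000))
    curve = assigner.count_barcodes(obs)
    assert curve.total_reads == 5000


# ---------------------------------------------------------------------------
# crude_anchor vs exhaustive brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_anchor(counts, literal=False):
    """Independent evaluation: per-rank log-log derivative, floor-binned
    0.001-wide windows of log10(rank), median per window, steepest descent."""
    windows = {}
    for i in range(1, len(counts)):  # 1-based rank i, derivative uses i, i+1
        d = (math.log10(counts[i]) - math.log10(counts[i - 1])) / (
            math.log10(i + 1) - math.log10(i)
        )
        w = math.floor(math.log10(i) / 0.001)
        windows.setdefault(w, []).append(d)
    med = {w: statistics.median(v) for w, v in windows.items()}
    if literal:
        w_star = max(sorted(med), key=lambda w: med[w])
    else:
        w_star = max(sorted(med), key=lambda w: abs(med[w]))
    return max(int(round(10 ** (0.001 * w_star))), 1)


def test_two_plateau_curve_knee_at_100():
    counts = np.array([1000] * 100 + [10] * 900)
    assert assigner.crude_anchor(counts) == 100
    assert brute_force_anchor(counts) == 100


def test_constant_curve_has_no_knee():
    with pytest.raises(ValueError, match="no knee"):
        assigner.crude_anchor(np.array([5] * 50))


@pytest.mark.parametrize("seed", range(6))
def test_crude_anchor_matches_brute_force_on_random_curves(seed):
    rng = np.random.default_rng(seed)
    n_true = int(rng.integers(50, 400))
    true_counts = np.sort(rng.integers(500, 5000, n_true))[::-1]
    noise = np.sort(rng.integers(1, 20, int(rng.integers(1000, 5000))))[::-1]
    counts = np.concatenate([true_counts, noise])
    assert assigner.crude_anchor(counts) == brute_force_anchor(counts)


def test_crude_anchor_literal_mode_matches_oracle():
    counts = np.array([1000] * 100 + [10] * 900)
    assert assigner.crude_anchor(counts, literal=True) == brute_force_anchor(
        counts, literal=True
    )


# ---------------------------------------------------------------------------
# extend_anchor
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "cr,n,expected",
    [(1000, 10_000, 1100), (1, 10, 2), (95, 100, 100), (10, 10, 10)],
)
def test_extend_anchor(cr, n, expected):
    assert assigner.extend_anchor(cr, n) == expected


# ---------------------------------------------------------------------------
# merge_barcodes_ld
# ---------------------------------------------------------------------------

def test_merge_absorbs_within_two_ld():
    cbs = ["A" * 16, "A" * 15 + "T"]
    merge_map, retained, counts = assigner.merge_barcodes_ld(cbs, [100, 3])
    assert merge_map[cbs[1]] == cbs[0]
    assert retained == [cbs[0]]
    assert counts[cbs[0]] == 103


def test_merge_keeps_distant_barcodes():
    cbs = ["A" * 16, "A" * 13 + "TTT"]
    merge_map, retained, _ = assigner.merge_barcodes_ld(cbs, [10, 5])
    assert len(retained) == 2


def test_merge_chain_is_one_directional():
    # B within 2 LD of A is absorbed; C is within 2 LD of B only, and B is
    # no longer available as an absorber, so C is retained
    a = "AAAAAAAAAAAAAAAA"
    b = "AAAAAAAAAAAAAATT"   # LD 2 from A
    c = "AAAAAAAAAAAATTTT"   # LD 2 from B, LD 4 from A
    merge_map, retained, counts = assigner.merge_barcodes_ld([a, b, c], [100, 50, 10])
    assert merge_map == {a: a, b: a, c: c}
    assert retained == [a, c]
    assert counts == {a: 150, c: 10}


def test_merge_tie_prefers_lexicographically_smaller_absorber():
    x = "AAAAAAAAAAAAAAAC"
    y = "AAAAAAAAAAAAAAAG"
    z = "AAAAAAAAAAAAAAAT"  # LD 1 from both
    merge_map, _, _ = assigner.merge_barcodes_ld([x, y, z], [50, 50, 5])
    assert merge_map[z] == x


@settings(max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.text(alphabet="ACGT", min_size=8, max_size=8),
                          st.integers(1, 500)), min_size=1, max_size=40))
def test_merge_conserves_mass_and_absorbers_are_final(pairs):
    seen = {}
    for cb, n in pairs:
        seen[cb] = seen.get(cb, 0) + n
    cbs, counts = list(seen), [seen[c] for c in seen]
    merge_map, retained, merged = assigner.merge_barcodes_ld(cbs, counts)
    assert sum(merged.values()) == sum(counts)
    for cb, absorber in merge_map.items():
        assert merge_map[absorber] == absorber  # absorbers never absorbed
    assert set(retained) == {c for c in merge_map if merge_map[c] == c}


# ---------------------------------------------------------------------------
# gene-count filter and deconvolution
# ---------------------------------------------------------------------------

def test_filter_by_gene_count_boundary():
    counts = {"a": 299, "b": 300, "c": 301}
    assert assigner.filter_by_gene_count(["a", "b", "c"], counts) == ["b", "c"]
    assert assigner.filter_by_gene_count(["a", "b"], counts, min_genes=0) == ["a", "b"]


def test_deconvolute_assigns_via_merge_map():
    a = "A" * 16
    a1 = "A" * 15 + "T"
    merge_map = {a: a, a1: a}
    cells, dropped = assigner.deconvolute(
        [("r1", a), ("r2", a1), ("r3", "G" * 16)], merge_map, [a]
    )
    assert cells[a] == ["r1", "r2"]
    assert dropped == 1


def test_deconvolute_empty_final_list_drops_all():
    cells, dropped = assigner.deconvolute([("r1", "A" * 16)], {}, [])
    assert cells == {} and dropped == 1
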