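import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from scnanopipe import simulator, stats
from scnanopipe.stats import GroupDesign


# ---------------------------------------------------------------------------
# chi_square vs the scipy oracle
# ---------------------------------------------------------------------------

def test_chi_square_hand_derivable_table():
    # margins 100/100 and 140/60: sum (O-E)^2/E = 2*(400/70 + 400/30) = 38.095...
    stat, p, df = stats.chi_square([[50, 50], [90, 10]])
    assert stat == pytest.approx(2 * (400 / 70 + 400 / 30), rel=1e-12)
    assert stat == pytest.approx(38.10, abs=0.01)
    assert df == 1


def test_chi_square_identical_rows_is_null():
    stat, p, df = stats.chi_square([[25, 75], [25, 75]])
    assert stat == 0.0
    assert p == 1.0


def test_chi_square_2x3_df():
    _, _, df = stats.chi_square([[10, 20, 30], [30, 20, 10]])
    assert df == 2


def test_chi_square_zero_margin_dropped_and_degenerate_p1():
    # a zero column drops out; the remainder is still 2x2
    stat, p, df = stats.chi_square([[10, 0, 20], [5, 0, 25]])
    stat2, p2, df2 = stats.chi_square([[10, 20], [5, 25]])
    assert (stat, p, df) == (stat2, p2, df2)
    # degenerate below 2x2 -> p = 1
    assert stats.chi_square([[10, 0], [20, 0]]) == (0.0, 1.0, 0)


@pytest.mark.parametrize("seed", range(10))
def test_chi_square_matches_scipy_oracle(seed):
    rng = np.random.default_rng(seed)
    r, c = rng.integers(2, 5, 2)
    table = rng.integers(1, 200, (r, c))
    stat, p, df = stats.chi_square(table)
    o_stat, o_p, o_df, _ = sps.chi2_contingency(table, correction=False)
    assert stat == pytest.approx(o_stat, rel=1e-10)
    assert p == pytest.approx(o_p, rel=1e-10, abs=1e-300)
    assert df == o_df


# ---------------------------------------------------------------------------
# bh_adjust vs the statsmodels oracle
# ---------------------------------------------------------------------------

def test_bh_adjust_hand_example():
    # q_i = p_i * n / i with step-up monotonicity: all become 0.03
    out = stats.bh_adjust([0.01, 0.02, 0.03])
    assert np.allclose(out, [0.03, 0.03, 0.03])


def test_bh_adjust_trivial_cases():
    assert np.allclose(stats.bh_adjust([0.2]), [0.2])
    assert np.allclose(stats.bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    assert stats.bh_adjust([]).size == 0


@pytest.mark.parametrize("seed", range(10))
def test_bh_adjust_matches_statsmodels_oracle(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(int(rng.integers(1, 200)))
    mine = stats.bh_adjust(p)
    _, oracle, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(mine, oracle, rtol=1e-10)


# ---------------------------------------------------------------------------
# dci_test
# ---------------------------------------------------------------------------

def _toy_matrix(counts, cells):
    return pd.DataFrame(counts, columns=cells)


def test_dci_skips_sporadic_and_single_isoform_genes(rng):
    cells = [f"A{j}" for j in range(100)] + [f"B{j}" for j in range(100)]
    labels = {c: c[0] for c in cells}
    m = pd.DataFrame(0.0, index=["G1.T1", "G1.T2", "G2.T1", "G3.T1", "G3.T2"],
                     columns=cells)
    # G1 expressed in 3% of cells in both groups -> skipped
    for c in cells[:3] + cells[100:103]:
        m.loc["G1.T1", c] = 2
    # G2 has a single isoform -> excluded
    m.loc["G2.T1"] = 5
    # G3 well expressed in group A only (still tested: fails in one group only)
    m.loc["G3.T1", cells[:60]] = 3
    m.loc["G3.T2", cells[:60]] = 1
    iso_gene = {t: t.split(".")[0] for t in m.index}
    res = stats.dci_test(m, iso_gene, GroupDesign(labels, "A", "B"))
    assert {r.gene for r in res} == {"G3"}


def test_dci_planted_switch_detected_with_distinct_mdts(rng):
    matrix, iso_gene, labels = simulator.simulate_isoform_counts(
        rng, n_genes=30, cells_per_group=200, mol_per_cell=5.0,
        shift=0.6, base_mix=0.5,
    )
    res = stats.dci_test(matrix, iso_gene, GroupDesign(labels, "A", "B"))
    assert len(res) == 30
    detected = [r for r in res if r.is_dci]
    assert len(detected) >= 29
    for r in detected:
        assert r.mdt_a != r.mdt_b  # composition switch flips the dominant isoform
        assert max(abs(d) for d in r.prevalence_diff.values()) >= 0.10
        assert r.adjusted_p < 0.05


def test_dci_prevalences_are_probabilities(rng):
    matrix, iso_gene, labels = simulator.simulate_isoform_counts(
        rng, n_genes=20, cells_per_group=50, shift=0.3
    )
    res = stats.dci_test(matrix, iso_gene, GroupDesign(labels, "A", "B"))
    for r in res:
        for d in (r.prevalence_a, r.prevalence_b):
            assert all(0.0 <= v <= 1.0 for v in d.values())


def test_dci_monotone_in_prevalence_threshold(rng):
    matrix, iso_gene, labels = simulator.simulate_isoform_counts(
        rng, n_genes=60, cells_per_group=100, shift=0.25
    )
    design = GroupDesign(labels, "A", "B")
    n_loose = sum(r.is_dci for r in stats.dci_test(matrix, iso_gene, design,
                                                   prev_diff=0.05))
    n_tight = sum(r.is_dci for r in stats.dci_test(matrix, iso_gene, design,
                                                   prev_diff=0.20))
    assert n_tight <= n_loose


def test_dci_empty_group_errors():
    m = pd.DataFrame([[1.0]], index=["G1.T1"], columns=["x"])
    with pytest.raises(ValueError, match="empty comparison group"):
        stats.dci_test(m, {"G1.T1": "G1"}, GroupDesign({"x": "A"}, "A", "B"))


# ---------------------------------------------------------------------------
# demut_test
# ---------------------------------------------------------------------------

def _states_row(mut_a, cov_a, mut_b, cov_b, n_a=100, n_b=100):
    cells = [f"A{j}" for j in range(n_a)] + [f"B{j}" for j in range(n_b)]
    row = {}
    for j, c in enumerate(cells):
        if c.startswith("A"):
            row[c] = ("mutant" if j < mut_a else
                      "wild-type" if j < cov_a else "missing")
        else:
            k = j - n_a
            row[c] = ("mutant" if k < mut_b else
                      "wild-type" if k < cov_b else "missing")
    return pd.DataFrame([row], index=["locus0"]), {c: c[0] for c in cells}


def test_demut_clear_expansion_detected():
    states, labels = _states_row(30, 100, 5, 100)
    res = stats.demut_test(states, GroupDesign(labels, "A", "B"))
    assert len(res) == 1
    r = res[0]
    oracle, op, _, _ = sps.chi2_contingency([[30, 70], [5, 95]], correction=False)
    assert r.statistic == pytest.approx(oracle, rel=1e-10)
    assert r.freq_diff == pytest.approx(0.25)
    assert r.is_demut


def test_demut_small_frequency_gap_never_flagged():
    states, labels = _states_row(12, 100, 7, 100)
    res = stats.demut_test(states, GroupDesign(labels, "A", "B"))
    assert res[0].freq_diff == pytest.approx(0.05)
    assert not res[0].is_demut


def test_demut_prefilter_skips_low_frequency_loci():
    states, labels = _states_row(3, 100, 3, 100)  # 3% in both groups
    assert stats.demut_test(states, GroupDesign(labels, "A", "B")) == []


def test_demut_excludes_uncovered_cells():
    # 10 mutant of 20 covered in A (50%) even though 100 cells exist
    states, labels = _states_row(10, 20, 2, 100)
    res = stats.demut_test(states, GroupDesign(labels, "A", "B"))
    assert res[0].freq_a == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# one_vs_rest
# ---------------------------------------------------------------------------

def test_one_vs_rest_runs_per_group(rng):
    matrix, iso_gene, labels = simulator.simulate_isoform_counts(
        rng, n_genes=10, cells_per_group=30, shift=0.0
    )
    three = {c: (g if c != "A0" else "C") for c, g in labels.items()}
    out = stats.one_vs_rest(
        three, lambda d: stats.dci_test(matrix, iso_gene, d)
    )
    assert set(out) == {"A", "B", "C"}


def test_one_vs_rest_null_makes_no_discoveries(rng):
    matrix, iso_gene, labels = simulator.simulate_isoform_counts(
        rng, n_genes=100, cells_per_group=100, shift=0.0
    )
    out = stats.one_vs_rest(labels, lambda d: stats.dci_test(matrix, iso_gene, d))
    for results in out.values():
        assert sum(r.is_dci for r in results) <= 5  # BH at 5% on true nulls
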