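import numpy as np
import pytest

from scnanopipe import scanner
from scnanopipe.io_formats import RawRead
from scnanopipe.scanner import AdapterConfig, Rejection, TaggedRead, revcomp


CFG = AdapterConfig()


def _mismatched(adapter: str, positions) -> str:
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(adapter)
    for p in positions:
        out[p] = flip[out[p]]
    return "".join(out)


def _make_read(read_id="r", cb="A" * 16, umi="C" * 12, insert="ACG" * 100,
               polyt="T" * 20, cfg=CFG):
    seq = cfg.r1_adapter + cb + umi + polyt + insert + cfg.tso_adapter
    return RawRead(read_id, seq, [30] * len(seq))


# ---------------------------------------------------------------------------
# locate_adapter
# ---------------------------------------------------------------------------

def test_exact_adapter_found_with_identity_one():
    seq = "GGGGG" + CFG.r1_adapter + "A" * 80
    hit = scanner.locate_adapter(seq, CFG.r1_adapter, CFG, end="5p")
    assert hit is not None
    assert hit.identity == 1.0
    assert (hit.start, hit.end) == (5, 5 + len(CFG.r1_adapter))


def test_six_mismatches_in_22nt_still_passes_70pct():
    # 16/22 ~ 0.727 >= 0.70
    bad = _mismatched(CFG.r1_adapter, [0, 4, 8, 12, 16, 20])
    hit = scanner.locate_adapter("GG" + bad + "A" * 80, CFG.r1_adapter, CFG, "5p")
    assert hit is not None
    assert hit.identity == pytest.approx(16 / 22)


def test_heavily_randomized_adapter_rejected():
    # 40% of bases flipped -> identity below the 70% acceptance threshold
    rng = np.random.default_rng(0)
    for _ in range(10):
        pos = rng.choice(len(CFG.r1_adapter), 9, replace=False)
        bad = _mismatched(CFG.r1_adapter, pos)
        hit = scanner.locate_adapter("GG" + bad + "A" * 80, CFG.r1_adapter, CFG, "5p")
        assert hit is None


def _gotoh_semiglobal(target: str, query: str, cfg: AdapterConfig) -> float:
    """Affine-gap semi-global DP oracle: query aligned end-to-end, target
    flanks free. Returns the optimal score."""
    neg = float("-inf")
    m, n = len(target), len(query)
    # M[i][j]: best ending in match/mismatch of t[i-1], q[j-1]
    M = [[neg] * (n + 1) for _ in range(m + 1)]
    X = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in query (consume target)
    Y = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in target (consume query)
    for i in range(m + 1):
        M[i][0] = 0.0  # free leading target flank
    for j in range(1, n + 1):
        Y[0][j] = cfg.gap_open + cfg.gap_extend * (j - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = cfg.match if target[i - 1] == query[j - 1] else cfg.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + cfg.gap_open, X[i - 1][j] + cfg.gap_extend)
            Y[i][j] = max(M[i][j - 1] + cfg.gap_open, Y[i][j - 1] + cfg.gap_extend)
    best = neg
    for i in range(m + 1):  # free trailing target flank
        best = max(best, M[i][n], Y[i][n])
    return best


@pytest.mark.parametrize("seed", range(8))
def test_alignment_score_matches_dp_oracle(seed):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    adapter = "".join(bases[rng.integers(0, 4, 18)])
    target = "".join(bases[rng.integers(0, 4, 45)])
    # embed a noisy copy of the adapter
    noisy = list(adapter)
    for p in rng.choice(len(noisy), 3, replace=False):
        noisy[p] = bases[rng.integers(0, 4)]
    pos = int(rng.integers(0, len(target) - len(adapter)))
    target = target[:pos] + "".join(noisy) + target[pos + len(adapter):]
    cfg = AdapterConfig(search_window=100, min_identity=0.01)
    hit = scanner.locate_adapter(target, adapter, cfg, end="5p")
    oracle = _gotoh_semiglobal(target, adapter, cfg)
    assert hit is not None
    assert hit.score == pytest.approx(oracle)


def test_substitution_only_identity_matches_mismatch_count():
    bad = _mismatched(CFG.r1_adapter, [3, 9])
    hit = scanner.locate_adapter("AA" + bad + "C" * 60, CFG.r1_adapter, CFG, "5p")
    assert hit.identity == pytest.approx(20 / 22)


# ---------------------------------------------------------------------------
# scan_read
# ---------------------------------------------------------------------------

def test_scan_read_extracts_planted_cb_umi_insert():
    cb, umi, insert = "GATTACAGATTACAGA", "ACGTACGTACGT", "ACG" * 100
    read = _make_read(cb=cb, umi=umi, insert=insert)
    tagged = scanner.scan_read(read, CFG)
    assert isinstance(tagged, TaggedRead)
    assert tagged.raw_cb == cb
    assert tagged.raw_umi == umi
    assert tagged.insert_seq == insert
    assert tagged.orientation == "forward"


def test_scan_read_short_insert_rejected():
    read = _make_read(insert="ACG" * 50)  # 150 nt < 200
    result = scanner.scan_read(read, CFG)
    assert isinstance(result, Rejection)
    assert result.reason == "short_insert"


def test_scan_read_orientation_symmetry():
    read = _make_read(cb="GATTACAGATTACAGA", umi="ACGTACGTACGT")
    fwd = scanner.scan_read(read, CFG)
    rc = RawRead(read.read_id, revcomp(read.sequence), read.qualities[::-1])
    rev = scanner.scan_read(rc, CFG)
    assert isinstance(rev, TaggedRead)
    assert rev.orientation == "reverse-complemented"
    assert (rev.raw_cb, rev.raw_umi, rev.insert_seq) == (
        fwd.raw_cb, fwd.raw_umi, fwd.insert_seq
    )


def test_scan_read_missing_adapters():
    seq = "ACG" * 120
    no_r1 = scanner.scan_read(RawRead("x", seq, [30] * len(seq)), CFG)
    assert isinstance(no_r1, Rejection) and no_r1.reason == "no_r1"
    seq2 = CFG.r1_adapter + "A" * 16 + "C" * 12 + "T" * 20 + "ACG" * 100 + "G" * 27
    no_tso = scanner.scan_read(RawRead("x", seq2, [30] * len(seq2)), CFG)
    assert isinstance(no_tso, Rejection) and no_tso.reason == "no_tso"


def test_scan_read_too_short():
    result = scanner.scan_read(RawRead("x", "ACGT" * 10, [30] * 40), CFG)
    assert isinstance(result, Rejection) and result.reason == "short_read"


def test_polyt_trim_allows_sparse_mismatch():
    # one non-T per >=10 T's is absorbed; the insert must come back intact
    insert = "GCA" * 100
    polyt = "T" * 12 + "A" + "T" * 12
    read = _make_read(insert=insert, polyt=polyt)
    tagged = scanner.scan_read(read, CFG)
    assert isinstance(tagged, TaggedRead)
    assert tagged.insert_seq == insert


# ---------------------------------------------------------------------------
# scan_file / nanoqc
# ---------------------------------------------------------------------------

def test_scan_file_counts_and_determinism(tmp_path):
    from scnanopipe.io_formats import write_fastq, read_barcode_list

    reads = [_make_read(read_id=f"ok{j}") for j in range(6)]
    reads += [_make_read(read_id=f"short{j}", insert="ACG" * 30) for j in range(4)]
    fq = tmp_path / "in.fastq"
    write_fastq(reads, fq)
    out1, out2 = tmp_path / "b1.tsv.gz", tmp_path / "p1.fastq.gz"
    counts = scanner.scan_file(fq, out1, out2, CFG)
    assert counts["accepted"] == 6
    assert counts["short_insert"] == 4
    df = read_barcode_list(out1)
    assert list(df.columns) == ["read_id", "cb", "umi"]
    assert len(df) == 6
    # deterministic rerun
    out3, out4 = tmp_path / "b2.tsv.gz", tmp_path / "p2.fastq.gz"
    scanner.scan_file(fq, out3, out4, CFG)
    assert read_barcode_list(out3).equals(df)


def test_nanoqc_histogram_and_boundaries():
    reads = [
        RawRead("a", "A" * 900, [30] * 900),
        RawRead("b", "C" * 900, [20] * 900),
        RawRead("c", "G" * 1200, [10] * 1200),
    ]
    report = scanner.nanoqc(reads)
    assert report.length_histogram == {900: 2, 1200: 1}
    assert sum(report.length_histogram.values()) == report.n_reads == 3
    assert report.head_quality[0] == pytest.approx(20.0)

    empty = scanner.nanoqc([])
    assert empty.length_histogram == {}
    assert empty.n_reads == 0

    short = scanner.nanoqc([RawRead("s", "A" * 50, [15] * 50)])
    assert short.head_quality[49] == pytest.approx(15.0)
    assert np.isnan(short.head_quality[50])
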