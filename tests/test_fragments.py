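"""Preprocessing: fragment parsing, sweep-line loci, merging, matrix build."""

import gzip

import numpy as np
import pandas as pd
import pytest

from sebula.fragments import (
    DEFAULT_MAX_INSERT,
    FragmentRecord,
    GenomicInterval,
    build_matrix,
    default_autosomes,
    find_high_coverage_loci,
    fragments_to_matrix,
    merge_loci,
    read_fragments,
    read_hclc_tsv,
    write_hclc_tsv,
    write_matrix_dir,
)
from sebula.simulate import simulate_fragments


def brute_force_loci(intervals, min_depth=3, span=512):
    """Per-base coverage oracle for maximal depth >= min_depth runs."""
    cov = np.zeros(span, dtype=int)
    for s, e in intervals:
        cov[s:e] += 1
    hot = cov >= min_depth
    loci = []
    start = None
    for pos, h in enumerate(hot):
        if h and start is None:
            start = pos
        elif not h and start is not None:
            loci.append((start, pos))
            start = None
    if start is not None:
        loci.append((start, span))
    return loci


# ---------------------------------------------------------------------------
# sweep-line high-coverage loci
# ---------------------------------------------------------------------------


def test_sweepline_triple_stagger():
    ivs = [(0, 300), (50, 350), (100, 400)]
    assert find_high_coverage_loci(ivs) == [(100, 300)]


def test_sweepline_duplicates_add_depth():
    assert find_high_coverage_loci([(10, 20)] * 3) == [(10, 20)]
    assert find_high_coverage_loci([(10, 20)] * 2) == []


def test_sweepline_accepts_fragment_records():
    frags = [FragmentRecord("chr1", s, e, "BC") for s, e in [(0, 30), (5, 30), (10, 30)]]
    assert find_high_coverage_loci(frags) == [(10, 30)]


def test_sweepline_half_open_boundary():
    # third fragment starts exactly where another ends: depth never reaches 3
    assert find_high_coverage_loci([(0, 10), (0, 10), (10, 20)]) == []


def test_sweepline_empty_and_min_depth_one():
    assert find_high_coverage_loci([]) == []
    assert find_high_coverage_loci([(3, 7)], min_depth=1) == [(3, 7)]


def test_sweepline_matches_per_base_oracle_randomized():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        n = int(rng.integers(1, 12))
        starts = rng.integers(0, 480, size=n)
        lengths = rng.integers(1, 40, size=n)
        ivs = [(int(s), int(min(512, s + l))) for s, l in zip(starts, lengths)]
        ivs = [(s, e) for s, e in ivs if e > s]
        depth = int(rng.integers(1, 5))
        assert find_high_coverage_loci(ivs, min_depth=depth) == brute_force_loci(
            ivs, min_depth=depth
        ), ivs


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def union_oracle(intervals):
    """Event-based union keeping half-open touching intervals separate.

    Ends are processed before starts at the same coordinate, so coverage
    momentarily drops to zero at a shared boundary and the run splits.
    """
    events = sorted(
        [(s, 1) for s, _ in intervals] + [(e, 0) for _, e in intervals]
    )  # (coord, kind): kind 0 = end sorts before kind 1 = start at equal coord
    out, depth, start = [], 0, None
    for pos, kind in events:
        if kind == 1:
            if depth == 0:
                start = pos
            depth += 1
        else:
            depth -= 1
            if depth == 0:
                out.append((start, pos))
                start = None
    return out


def test_merge_examples_and_touching_stay_separate():
    assert merge_loci([[(0, 5), (3, 8)], [(10, 12)]]) == [(0, 8), (10, 12)]
    # half-open: [0,5) and [5,8) do not overlap
    assert merge_loci([[(0, 5)], [(5, 8)]]) == [(0, 5), (5, 8)]


def test_merge_order_invariant_idempotent_randomized():
    rng = np.random.default_rng(13)
    for _ in range(300):
        n = int(rng.integers(0, 10))
        ivs = []
        for _ in range(n):
            s = int(rng.integers(0, 950))
            ivs.append((s, s + int(rng.integers(1, 60))))
        merged = merge_loci([ivs])
        assert merged == union_oracle(ivs)
        perm = [ivs[i] for i in rng.permutation(len(ivs))]
        assert merge_loci([perm]) == merged
        assert merge_loci([merged]) == merged
        # output is sorted and pairwise disjoint under half-open semantics
        assert all(merged[i][1] <= merged[i + 1][0] for i in range(len(merged) - 1))


# ---------------------------------------------------------------------------
# fragment parsing
# ---------------------------------------------------------------------------


def write_fragments(path, rows, gz=True):
    opener = gzip.open if gz else open
    with opener(path, "wt") as fh:
        fh.write("# header comment\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def test_read_fragments_filters(tmp_path):
    p = tmp_path / "frags.tsv.gz"
    rows = [
        ("chr1", 100, 400, "AAA-1", 2),  # kept
        ("chr1", 0, 899, "AAA-1", 1),  # kept: insert 899 < 900
        ("chr1", 0, 900, "AAA-1", 1),  # dropped: insert not strictly < 900
        ("chrX", 100, 200, "AAA-1", 1),  # dropped: not autosome
        ("chr2", 100, 200, "BBB-1", 1),  # dropped: barcode not whitelisted
        ("2", 100, 200, "AAA-1", 1),  # kept: prefixless autosome name
    ]
    write_fragments(p, rows)
    recs = list(read_fragments(p, ["AAA-1"]))
    assert [(r.chrom, r.start, r.end, r.dup_count) for r in recs] == [
        ("chr1", 100, 400, 2),
        ("chr1", 0, 899, 1),
        ("2", 100, 200, 1),
    ]
    assert recs[0].insert_size == 300
    assert DEFAULT_MAX_INSERT == 900


def test_read_fragments_plain_text_and_four_columns(tmp_path):
    p = tmp_path / "frags.tsv"
    write_fragments(p, [("chr1", 5, 15, "AAA-1")], gz=False)
    (rec,) = read_fragments(p, ["AAA-1"])
    assert rec.dup_count == 1


def test_read_fragments_malformed_line_numbers(tmp_path):
    p = tmp_path / "bad.tsv"
    write_fragments(p, [("chr1", 5, 15, "AAA-1", 1), ("chr1", "x", 15, "AAA-1", 1)], gz=False)
    with pytest.raises(ValueError, match="line 3"):
        list(read_fragments(p, ["AAA-1"]))
    p2 = tmp_path / "short.tsv"
    write_fragments(p2, [("chr1", 5)], gz=False)
    with pytest.raises(ValueError, match="line 2"):
        list(read_fragments(p2, ["AAA-1"]))


def test_read_fragments_empty_whitelist_raises(tmp_path):
    p = tmp_path / "frags.tsv"
    write_fragments(p, [("chr1", 5, 15, "AAA-1", 1)], gz=False)
    with pytest.raises(ValueError, match="barcode set is empty"):
        list(read_fragments(p, []))


def test_read_fragments_warns_when_nothing_retained(tmp_path):
    p = tmp_path / "frags.tsv"
    write_fragments(p, [("chrX", 5, 15, "AAA-1", 1)], gz=False)
    with pytest.warns(UserWarning, match="no fragments retained"):
        list(read_fragments(p, ["AAA-1"]))


def test_default_autosomes():
    auto = default_autosomes()
    assert "chr1" in auto and "22" in auto
    assert "chrX" not in auto and "chrM" not in auto


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)


def test_build_matrix_overlap_semantics():
    merged = {"chr1": [(100, 200), (300, 400)]}
    frags = {
        "A": [FragmentRecord("chr1", 150, 160, "A")],  # hits locus 0
        "B": [FragmentRecord("chr1", 200, 250, "B")],  # touches locus 0 boundary: no hit
        "C": [FragmentRecord("chr1", 190, 310, "C")],  # spans both loci
    }
    msm = build_matrix(merged, frags, barcodes=["A", "B", "C"])
    # locus (300,400) hit only by C; B hits nothing so locus rows with no
    # cells are dropped only if NO cell hits them
    dense = msm.matrix.toarray()
    assert msm.hclc.tolist() == [1, 0, 2]
    assert dense.shape == (2, 3)


def test_fragments_to_matrix_end_to_end(tmp_path):
    p = tmp_path / "frags.tsv.gz"
    rows = []
    # cell A: one high-coverage locus on chr1 at [100,300) core
    for off in (0, 50, 100):
        rows.append(("chr1", 100 + off, 100 + off + 200, "A", 1))
    # cell B: overlapping locus shifted by 150; merged with A's locus
    for off in (0, 50, 100):
        rows.append(("chr1", 250 + off, 250 + off + 200, "B", 1))
    write_fragments(p, rows)
    msm = fragments_to_matrix(p, ["A", "B"])
    # A's fragments give depth >= 3 on [200,300), B's on [350,450); the loci
    # stay separate, and each cell has ordinary fragments overlapping both
    assert [(iv.start, iv.end) for iv in msm.loci] == [(200, 300), (350, 450)]
    assert msm.hclc.tolist() == [2, 2]
    # blacklist covering the locus removes it
    msm_bl = fragments_to_matrix(
        p, ["A", "B"], blacklist=[GenomicInterval("chr1", 0, 1000)]
    )
    assert msm_bl.n_loci == 0 and msm_bl.hclc.tolist() == [0, 0]


def test_simulate_fragments_hclc_truth(tmp_path):
    frag_path, bc_path, expected, is_doublet = simulate_fragments(
        tmp_path, n_singlets=40, n_loci=20, doublet_proportion=0.1, seed=5
    )
    barcodes = bc_path.read_text().split()
    msm = fragments_to_matrix(frag_path, barcodes)
    assert msm.hclc.tolist() == expected.tolist()
    labels = pd.read_csv(tmp_path / "labels.tsv", sep="\t")
    assert labels["is_doublet"].astype(bool).tolist() == is_doublet.tolist()


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------


def test_hclc_tsv_round_trip(tmp_path):
    s = pd.Series([3, 0, 17], index=pd.Index(["A", "B", "C"], name="barcode"), name="hclc")
    path = tmp_path / "hclc.tsv"
    write_hclc_tsv(s, path)
    back = read_hclc_tsv(path)
    pd.testing.assert_series_equal(back, s)
    # headerless variant
    path2 = tmp_path / "plain.tsv"
    path2.write_text("A\t3\nB\t0\nC\t17\n")
    pd.testing.assert_series_equal(read_hclc_tsv(path2), s)


def test_write_matrix_dir(tmp_path, small_dataset):
    write_matrix_dir(small_dataset.matrix, tmp_path)
    for name in ("matrix.mtx", "loci.bed", "barcodes.tsv", "hclc.tsv"):
        assert (tmp_path / name).exists()
    back = read_hclc_tsv(tmp_path / "hclc.tsv")
    assert back.to_numpy().tolist() == small_dataset.matrix.hclc.tolist()
    bed = (tmp_path / "loci.bed").read_text().splitlines()
    assert len(bed) == small_dataset.matrix.n_loci
    chrom, start, end = bed[0].split("\t")
    assert int(end) > int(start)
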