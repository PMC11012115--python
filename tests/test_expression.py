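"""Quantification: k-mer index, assignment, FPKM, normalization, criterion."""

import numpy as np
import pandas as pd
import pytest

from orexpress.expression import (
    build_expression_matrix,
    build_kmer_index,
    compute_criterion,
    expression_percent,
    fpkm,
    quantify_sample,
    rank_and_name,
)
from orexpress.synthetic import revcomp

RNG = np.random.default_rng(123)


def _random_seq(n):
    return "".join(np.array(list("ACGT"))[RNG.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# FPKM and normalization closed forms


def test_fpkm_formula_derived_example():
    # count 1000, length 1000 bp, 1e6 mapped fragments:
    # 1000 * 1e9 / (1000 * 1e6) = 1000
    assert fpkm(1000, 1000, 1_000_000) == 1000.0
    assert fpkm(0, 500, 10_000) == 0.0


def test_fpkm_scale_invariance():
    a = fpkm(120, 918, 50_000)
    b = fpkm(240, 918, 100_000)
    assert a == pytest.approx(b)


def test_fpkm_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        fpkm(1, 0, 100)
    with pytest.raises(ValueError):
        fpkm(1, 100, 0)


def test_expression_percent_printed_pairs():
    assert round(expression_percent(3.640, 983), 3) == 0.370
    assert round(expression_percent(0.543, 371), 3) == 0.146
    assert expression_percent(0.0, 371) == 0.0
    with pytest.raises(ValueError):
        expression_percent(1.0, 0.0)


# ---------------------------------------------------------------------------
# k-mer index


def test_identical_genes_are_unquantifiable():
    s = _random_seq(200)
    idx = build_kmer_index({"a": s, "b": s}, k=31)
    assert idx.unquantifiable == ["a", "b"]
    assert len(idx.codes) == 0


def test_reverse_complement_collapses_to_one_key():
    s = _random_seq(200)
    idx = build_kmer_index({"a": s, "b": revcomp(s)}, k=31)
    assert idx.unquantifiable == ["a", "b"], "a k-mer and its reverse complement are one key"


def test_private_kmers_map_to_their_gene():
    a, b = _random_seq(300), _random_seq(300)
    idx = build_kmer_index({"a": a, "b": b}, k=31)
    assert idx.unquantifiable == []
    # each gene keeps close to its full complement of k-mers
    counts = np.bincount(idx.gene_idx, minlength=2)
    assert min(counts) > 200


def test_short_gene_reported():
    idx = build_kmer_index({"tiny": "ACGT" * 5, "ok": _random_seq(300)}, k=31)
    assert "tiny" in idx.unquantifiable


def test_k_too_small_rejected():
    with pytest.raises(ValueError):
        build_kmer_index({"a": _random_seq(100)}, k=15)


# ---------------------------------------------------------------------------
# fragment assignment


def _write_pairs(path1, path2, pairs):
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, (s1, s2) in enumerate(pairs):
            q = "I" * len(s1)
            f1.write(f"@p{i}\n{s1}\n+\n{q}\n")
            q2 = "I" * len(s2)
            f2.write(f"@p{i}\n{s2}\n+\n{q2}\n")


def test_assignment_duplicates_and_unassigned(tmp_path):
    gene_a, gene_b = _random_seq(400), _random_seq(400)
    unrelated = _random_seq(400)
    idx = build_kmer_index({"a": gene_a, "b": gene_b}, k=31)

    frag_a = gene_a[50:250]
    pair_a = (frag_a[:100], revcomp(frag_a)[:100])
    frag_b = gene_b[10:310]
    pair_b = (frag_b[:100], revcomp(frag_b)[:100])
    pair_x = (unrelated[:100], revcomp(unrelated)[:100])

    pairs = [pair_a] * 5 + [pair_b, pair_x]  # pair_a duplicated 5x
    _write_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq", pairs)
    q = quantify_sample(tmp_path / "r1.fq", tmp_path / "r2.fq", idx, sample_id="s")
    assert q.counts == {"a": 1, "b": 1}, "duplicates count once"
    assert q.n_duplicates == 4
    assert q.n_unassigned == 1
    # count conservation: assigned + unassigned + duplicates = input pairs
    assert q.n_assigned + q.n_unassigned + q.n_duplicates == q.n_pairs


def test_conflicting_mates_are_unassigned(tmp_path):
    gene_a, gene_b = _random_seq(400), _random_seq(400)
    idx = build_kmer_index({"a": gene_a, "b": gene_b}, k=31)
    # mate 1 entirely from a, mate 2 entirely from b, equal vote counts
    pairs = [(gene_a[0:131], gene_b[0:131])]
    _write_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq", pairs)
    q = quantify_sample(tmp_path / "r1.fq", tmp_path / "r2.fq", idx)
    assert q.counts == {"a": 0, "b": 0}
    assert q.n_unassigned == 1


def test_count_conservation_full_scale(table2_run):
    for sid, q in table2_run["quants"].items():
        assert q.n_assigned + q.n_unassigned + q.n_duplicates == q.n_pairs


# ---------------------------------------------------------------------------
# expression matrix and criterion


def _toy_matrix():
    genes = {"or1": 900, "or2": 900, "ACTB": 1200}
    counts = pd.DataFrame(
        {"s1": [90, 0, 600], "s2": [0, 45, 300]}, index=["or1", "or2", "ACTB"]
    )

    class Q:
        def __init__(self, sid):
            self.sample_id = sid
            self.counts = counts[sid].to_dict()
            self.n_assigned = int(counts[sid].sum())

    return build_expression_matrix([Q("s1"), Q("s2")], genes)


def test_normalization_invariance_under_count_scaling():
    m = _toy_matrix()
    genes = {"or1": 900, "or2": 900, "ACTB": 1200}

    class Q:
        def __init__(self, sid, factor):
            self.sample_id = sid
            self.counts = {"or1": 90 * factor, "or2": 0, "ACTB": 600 * factor}
            self.n_assigned = 690 * factor

    m1 = build_expression_matrix([Q("s1", 1)], genes)
    m2 = build_expression_matrix([Q("s1", 2)], genes)
    pd.testing.assert_frame_equal(m1.expression_percent, m2.expression_percent)


def test_criterion_hand_pooled_2x2():
    pct = pd.DataFrame({"s1": [2.0, 1.0], "s2": [0.0, 1.0]}, index=["g1", "g2"])
    crit = compute_criterion(pct, ["g1", "g2"], control_samples=[])
    # pooled non-zero values {2, 1, 1} -> mean 4/3
    assert crit.criterion_value == pytest.approx(4.0 / 3.0)
    assert sorted(crit.contributing) == [("g1", "s1"), ("g2", "s1"), ("g2", "s2")]
    # cell exactly at the criterion is called; smaller cells are not
    assert bool(crit.calls.loc["g1", "s1"]) is True
    assert bool(crit.calls.loc["g2", "s1"]) is False


def test_criterion_equality_is_called():
    pct = pd.DataFrame({"s1": [3.0, 3.0]}, index=["g1", "g2"])
    crit = compute_criterion(pct, ["g1", "g2"], control_samples=[])
    assert crit.criterion_value == pytest.approx(3.0)
    assert crit.calls.all().all(), "expression equal to the criterion is expressed"


def test_criterion_single_cell():
    pct = pd.DataFrame({"s1": [5.0, 0.0]}, index=["g1", "g2"])
    crit = compute_criterion(pct, ["g1", "g2"], control_samples=[])
    assert crit.criterion_value == 5.0
    assert crit.calls.values.sum() == 1


def test_criterion_all_zero_errors():
    pct = pd.DataFrame({"s1": [0.0, 0.0]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="criterion undefined"):
        compute_criterion(pct, ["g1", "g2"], control_samples=[])


def test_criterion_missing_control_errors():
    pct = pd.DataFrame({"s1": [1.0]}, index=["g1"])
    with pytest.raises(ValueError, match="control samples"):
        compute_criterion(pct, ["g1"], control_samples=["nope"])


def test_criterion_control_pool_switch():
    pct = pd.DataFrame({"s1": [4.0], "ctl": [2.0]}, index=["g1"])
    with_ctl = compute_criterion(pct, ["g1"], ["ctl"], include_controls_in_pool=True)
    without = compute_criterion(pct, ["g1"], ["ctl"], include_controls_in_pool=False)
    assert with_ctl.criterion_value == pytest.approx(3.0)
    assert without.criterion_value == pytest.approx(4.0)
    assert with_ctl.negative_control_max == 2.0


def test_rank_and_name():
    fpkm_s = pd.Series({"a": 5.0, "b": 9.0})
    names = rank_and_name(fpkm_s, ["a", "b"])
    assert names["b"] == (1, "OR001") and names["a"] == (2, "OR002")
    tie = rank_and_name(pd.Series({"a": 5.0, "b": 5.0}), ["a", "b"])
    assert tie["a"][0] == 1 and tie["b"][0] == 2, "ties break by gene id"
    zero = rank_and_name(pd.Series({"b": 0.0, "a": 0.0}), ["a", "b"])
    assert zero["a"][0] == 1
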