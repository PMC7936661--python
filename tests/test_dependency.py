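import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import enum_fisher
from shortloop.dependency import (
    binarize_dependency,
    classify_pair,
    fisher_exact,
    pair_contingency,
    read_dependency_csv,
    screen_pairs,
)
from shortloop.synthdata import gen_dependency, write_dependency_csv


class TestBinarize:
    def test_threshold_is_strict(self):
        m = pd.DataFrame({"G": [-1.2, -1.0, 0.0]}, index=["c1", "c2", "c3"])
        b = binarize_dependency(m)
        assert b["G"].tolist() == [True, False, False]

    def test_missing_stays_missing(self):
        m = pd.DataFrame({"G": [-2.0, np.nan]}, index=["c1", "c2"])
        b = binarize_dependency(m)
        assert b["G"].iloc[0] is np.True_ or b["G"].iloc[0] == True  # noqa: E712
        assert pd.isna(b["G"].iloc[1])

    def test_boundary_flip_under_nonstrict_threshold(self):
        m = pd.DataFrame({"G": [-1.2, -1.0, -0.8]}, index=list("abc"))
        strict = binarize_dependency(m, threshold=-1.0)
        shifted = binarize_dependency(m, threshold=-1.0 + 1e-9)
        diff = strict["G"] != shifted["G"]
        assert diff.tolist() == [False, True, False]


class TestContingency:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 1, 0, 0], [1, 0, 1, 0], (1, 1, 1, 1)),
            ([1, 1, 1, 0], [0, 0, 0, 0], (0, 3, 0, 1)),
            ([1, 0, 1, 0], [1, 0, 1, 0], (2, 0, 0, 2)),
        ],
    )
    def test_hand_counted_tables(self, x, y, expected):
        b = pd.DataFrame({"X": [bool(v) for v in x], "Y": [bool(v) for v in y]}).astype(object)
        assert pair_contingency(b, "X", "Y") == expected

    def test_missing_excluded_pairwise(self):
        b = pd.DataFrame({
            "X": [True, True, np.nan, False],
            "Y": [True, False, True, False],
        }).astype(object)
        assert pair_contingency(b, "X", "Y") == (1, 1, 0, 1)

    def test_unknown_gene_errors(self):
        b = pd.DataFrame({"X": [True]}).astype(object)
        with pytest.raises(KeyError):
            pair_contingency(b, "X", "Z")


class TestFisher:
    def test_greater_tail_exact_value(self):
        assert fisher_exact((3, 1, 1, 3), side="greater") == pytest.approx(17 / 70)

    def test_less_tail_exact_value(self):
        assert fisher_exact((0, 5, 5, 0), side="less") == pytest.approx(1 / 252)

    def test_zero_margin_gives_one(self):
        for side in ("greater", "less", "two-sided"):
            assert fisher_exact((0, 0, 3, 4), side=side) == 1.0

    @given(
        st.tuples(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
        .filter(lambda t: sum(t) <= 30),
        st.sampled_from(["greater", "less", "two-sided"]),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_full_enumeration_oracle(self, table, side):
        a, b, c, d = table
        assert fisher_exact(table, side=side) == pytest.approx(
            enum_fisher(a, b, c, d, side), rel=1e-8, abs=1e-12
        )


class TestClassify:
    def test_mutual_exclusive_rule(self):
        call = classify_pair((0, 3, 4, 60))
        assert call.klass == "mutual_exclusive"

    def test_co_occurring_rule(self):
        call = classify_pair((2, 1, 0, 64))
        assert call.klass == "co_occurring"

    def test_essentiality_cap_forces_neither(self):
        # one gene dependent in 40 of 67 lines: over the <50% cap
        call = classify_pair((0, 40, 3, 24))
        assert call.klass == "neither"

    def test_single_line_arms_are_neither(self):
        assert classify_pair((0, 1, 3, 63)).klass == "neither"
        assert classify_pair((1, 0, 0, 66)).klass == "neither"

    def test_symmetric_in_gene_order(self):
        a = classify_pair((0, 5, 2, 60))
        b = classify_pair((0, 2, 5, 60))
        assert a.klass == b.klass
        assert a.p_me == pytest.approx(b.p_me)
        assert a.p_co == pytest.approx(b.p_co)

    def test_classes_mutually_exclusive_by_construction(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            counts = tuple(int(v) for v in rng.integers(0, 10, size=4))
            call = classify_pair(counts)
            me = call.n_both == 0 and call.n_x_only >= 2 and call.n_y_only >= 2
            co = call.n_both >= 2
            assert not (me and co and call.klass not in ("mutual_exclusive", "co_occurring", "neither"))
            assert call.klass in ("mutual_exclusive", "co_occurring", "neither")


class TestScreen:
    def test_planted_classes_recovered(self, tmp_path):
        planted = {
            ("ME1_A", "ME1_B"): "mutual_exclusive",
            ("ME2_A", "ME2_B"): "mutual_exclusive",
            ("CO1_A", "CO1_B"): "co_occurring",
        }
        scores, truth = gen_dependency(n_lines=67, planted=planted, n_decoy_genes=6, seed=11)
        path = tmp_path / "dep.csv"
        write_dependency_csv(scores, path)
        binary = binarize_dependency(read_dependency_csv(path))
        pairs = list(planted) + [("DECOY0", "DECOY1"), ("DECOY2", "DECOY3")]
        calls, summary = screen_pairs(binary, pairs)
        got = {(c.gene_x, c.gene_y): c.klass for c in calls}
        for pair, klass in planted.items():
            assert got[pair] == klass
        assert summary["mutual_exclusive"] == 2
        assert summary["co_occurring"] == 1
        assert got[("DECOY0", "DECOY1")] == "neither"

    def test_empty_pairs(self):
        scores, _ = gen_dependency(seed=0)
        calls, summary = screen_pairs(binarize_dependency(scores), [])
        assert calls == [] and sum(summary.values()) == 0

    def test_degenerate_pair_rejected(self):
        scores, _ = gen_dependency(seed=0)
        with pytest.raises(ValueError):
            screen_pairs(binarize_dependency(scores), [("GME_A", "GME_A")])

    def test_absent_gene_skipped(self):
        scores, _ = gen_dependency(seed=0)
        calls, _ = screen_pairs(binarize_dependency(scores), [("GME_A", "NOPE")])
        assert calls == []
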