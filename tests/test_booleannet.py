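import numpy as np
import pandas as pd
import pytest

from implinet import booleannet, stepminer
from implinet.booleannet import (
    CONVERSE,
    QuadrantCounts,
    all_pairs,
    classify_pair,
    permutation_fdr,
    quadrant_counts,
    sparseness,
)
from implinet.stepminer import HIGH, INTERMEDIATE, LOW

from conftest import step_matrix

L, H, I = LOW, HIGH, INTERMEDIATE


def codes(*blocks):
    """Concatenate (code, count) blocks into an int8 vector."""
    return np.concatenate([np.full(n, c, dtype=np.int8) for c, n in blocks])


class TestQuadrantCounts:
    def test_direct_counting(self):
        a = [L, L, L, L, H, H, H, H]
        b = [L, L, L, H, H, H, H, H]
        c = quadrant_counts(a, b)
        assert (c.n00, c.n01, c.n10, c.n11) == (3, 1, 0, 4)

    def test_intermediate_excluded(self):
        a = [L, I, L, H]
        b = [L, L, H, H]
        c = quadrant_counts(a, b)
        assert c.n == 3 and c.n00 == 1

    def test_degenerate_all_high(self):
        c = quadrant_counts([H] * 5, [H] * 5)
        assert (c.n00, c.n01, c.n10, c.n11) == (0, 0, 0, 5)


class TestSparseness:
    def test_stated_arithmetic(self):
        # n=100, 50/50 margins, 2 observations in the (low, high) quadrant
        c = QuadrantCounts(n00=48, n01=2, n10=2, n11=48)
        s, p = sparseness(c, (0, 1))
        assert s == pytest.approx((25 - 2) / 5) == pytest.approx(4.6)
        assert p == pytest.approx(0.04)

    def test_observed_equals_expected_gives_zero(self):
        c = QuadrantCounts(n00=25, n01=25, n10=25, n11=25)
        assert sparseness(c, (0, 1))[0] == pytest.approx(0.0)

    def test_empty_quadrant(self):
        c = QuadrantCounts(n00=50, n01=0, n10=25, n11=25)
        s, p = sparseness(c, (0, 1))
        assert s == pytest.approx(np.sqrt(50 * 25 / 100)) and p == 0.0

    def test_untestable_zero_margin(self):
        c = QuadrantCounts(n00=0, n01=0, n10=5, n11=5)
        s, p = sparseness(c, (0, 0))
        assert np.isnan(s) and np.isnan(p)


class TestClassifyPair:
    def test_identity_pair_is_equivalent(self):
        a = codes((L, 50), (H, 50))
        assert classify_pair(a, a).relation == "equivalent"

    def test_complement_pair_is_opposite(self):
        a = codes((L, 50), (H, 50))
        b = codes((H, 50), (L, 50))
        assert classify_pair(a, b).relation == "opposite"

    def test_nested_pattern_gives_asymmetric_low_low(self):
        # b HIGH only where a is HIGH: sparse (a low, b high) quadrant only
        a = codes((L, 50), (H, 50))
        b = codes((L, 75), (H, 25))
        res = classify_pair(a, b)
        assert res.relation == "low=>low"
        assert res.s1 == pytest.approx(np.sqrt(50 * 25 / 100))
        assert res.p1 == 0.0

    def test_too_few_samples_skipped(self):
        a = codes((L, 5), (H, 5))
        res = classify_pair(a, a, min_samples=20)
        assert res.relation == "none" and not res.passes

    def test_untestable_quadrants_are_nonsparse(self):
        a = codes((H, 40))
        b = codes((L, 20), (H, 20))
        assert classify_pair(a, b).relation == "none"

    @pytest.mark.parametrize("n_b_high", [25, 50, 75])
    def test_contrapositive_symmetry(self, n_b_high):
        rng = np.random.default_rng(n_b_high)
        a = rng.permuted(codes((L, 50), (H, 50)))
        b = np.where(a == H, rng.permuted(codes((L, 100 - n_b_high), (H, n_b_high)))[:100], L)
        fwd = classify_pair(a, b).relation
        rev = classify_pair(b, a).relation
        assert rev == CONVERSE[fwd]


class TestAllPairs:
    def test_planted_three_gene_relations(self):
        m = step_matrix({"A": [0, 1], "B": [0, 1], "C": [1, 0]})
        ternary = stepminer.ternarize(m, min_per_side=3)
        table = all_pairs(ternary).set_index(["gene_a", "gene_b"])
        assert table.loc[("A", "B"), "relation"] == "equivalent"
        assert table.loc[("A", "C"), "relation"] == "opposite"
        assert table.loc[("B", "C"), "relation"] == "opposite"

    def test_single_gene_empty_table(self):
        m = step_matrix({"A": [0, 1]})
        assert len(all_pairs(stepminer.ternarize(m))) == 0

    def test_uninformative_gene_absent(self):
        m = step_matrix({"A": [0, 1], "B": [0, 1]})
        m.loc["flat"] = 6.0
        table = all_pairs(stepminer.ternarize(m))
        assert "flat" not in set(table["gene_a"]) | set(table["gene_b"])

    def test_statistics_match_brute_force(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(
            rng.normal(rng.choice([4.0, 8.0], size=(12, 60)), 0.4),
            index=[f"g{i}" for i in range(12)],
            columns=[f"s{i}" for i in range(60)],
        )
        ternary = stepminer.ternarize(m, min_per_side=2)
        table = all_pairs(ternary, min_samples=10)
        inf = ternary.informative_codes()
        for row in table.itertuples(index=False):
            res = classify_pair(
                inf.loc[row.gene_a].to_numpy(),
                inf.loc[row.gene_b].to_numpy(),
                min_samples=10,
            )
            assert res.relation == row.relation
            if res.passes:
                assert res.s1 == pytest.approx(row.S1)
                assert res.p1 == pytest.approx(row.p1)

    def test_sample_permutation_invariance(self):
        m = step_matrix({"A": [0, 1], "B": [0, 1], "C": [1, 0]})
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.shape[1])
        t1 = all_pairs(stepminer.ternarize(m))
        t2 = all_pairs(stepminer.ternarize(m.iloc[:, perm]))
        pd.testing.assert_frame_equal(t1, t2)


class TestPermutationFDR:
    def test_planted_structure_fdr_near_zero(self):
        m = step_matrix({f"g{i}": [0, 1] for i in range(5)} | {f"h{i}": [1, 0] for i in range(5)})
        ternary = stepminer.ternarize(m)
        fdr = permutation_fdr(ternary, n_perm=10, seed=3)
        assert fdr < 0.05

    def test_seed_determinism(self):
        m = step_matrix({f"g{i}": [0, 1] for i in range(4)})
        ternary = stepminer.ternarize(m)
        assert permutation_fdr(ternary, n_perm=5, seed=11) == permutation_fdr(
            ternary, n_perm=5, seed=11
        )

    def test_by_relation_scope(self):
        m = step_matrix({f"g{i}": [0, 1] for i in range(4)})
        ternary = stepminer.ternarize(m)
        fdrs = permutation_fdr(ternary, n_perm=5, seed=1, by_relation=True)
        assert set(fdrs) == set(booleannet.RELATIONS[:-1])
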