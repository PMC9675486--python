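import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from implinet import scoring
from implinet.network import SignaturePath
from implinet.stepminer import StepFit
from implinet.scoring import (
    bh_adjust,
    classification_report,
    composite_score,
    normalize_gene,
    roc_auc,
    welch_t,
)


def make_fit(threshold, low=None, high=None, n=10):
    low = threshold - 2 if low is None else low
    high = threshold + 2 if high is None else high
    return StepFit(
        threshold=threshold, split_index=n // 2, low_mean=low, high_mean=high,
        sse=0.0, f_statistic=np.inf, n=n,
    )


class TestNormalize:
    def test_centering_and_scale(self):
        fit = make_fit(2.5)
        z = normalize_gene([4.0, 2.5], fit)
        assert z[0] == pytest.approx(0.5) and z[1] == 0.0

    def test_shift_invariance(self):
        fit = make_fit(2.5)
        shifted = make_fit(2.5 + 3.0)
        assert normalize_gene([4.0], fit)[0] == pytest.approx(normalize_gene([7.0], shifted)[0])

    def test_degenerate_fit_gives_zeros(self):
        fit = StepFit(2.0, 2, 2.0, 2.0, 0.0, 0.0, 4)
        assert (normalize_gene([1.0, 5.0], fit) == 0).all()


class TestCompositeScore:
    @pytest.fixture()
    def two_gene_setup(self):
        # z-values 0.5 and 0.1 for the single sample (threshold 0, scale 3)
        matrix = pd.DataFrame({"s1": [1.5, 0.3]}, index=["g1", "g2"])
        fits = pd.DataFrame(
            {"threshold": [0.0, 0.0], "low_mean": [-2.0, -2.0], "high_mean": [2.0, 2.0]},
            index=["g1", "g2"],
        )
        return matrix, fits

    def test_weighted_cluster_mean(self, two_gene_setup):
        matrix, fits = two_gene_setup
        path = SignaturePath(cluster_ids=["C1"], weights=[2])
        score = composite_score(path, matrix, fits, {"C1": ["g1", "g2"]})
        assert score["s1"] == pytest.approx(2 * (0.5 + 0.1) / 2) == pytest.approx(0.6)

    def test_linear_in_weights(self, two_gene_setup):
        matrix, fits = two_gene_setup
        members = {"C1": ["g1"], "C2": ["g2"]}
        s1 = composite_score(SignaturePath(["C1", "C2"], [1, 2]), matrix, fits, members)
        s2 = composite_score(SignaturePath(["C1", "C2"], [2, 4]), matrix, fits, members)
        assert s2["s1"] == pytest.approx(2 * s1["s1"])

    def test_down_cluster_below_threshold_contributes_positively(self, two_gene_setup):
        matrix, fits = two_gene_setup
        matrix = -matrix  # both genes below threshold
        path = SignaturePath(cluster_ids=["C1"], weights=[-1])
        score = composite_score(path, matrix, fits, {"C1": ["g1", "g2"]})
        assert score["s1"] > 0

    def test_missing_gene_dropped_and_empty_cluster_nan(self, two_gene_setup):
        matrix, fits = two_gene_setup
        matrix.loc["g2", "s1"] = np.nan
        path = SignaturePath(cluster_ids=["C1"], weights=[1])
        score = composite_score(path, matrix, fits, {"C1": ["g1", "g2"]})
        assert score["s1"] == pytest.approx(0.5)  # mean over the present member
        matrix.loc["g1", "s1"] = np.nan
        with pytest.warns(UserWarning, match="entire cluster"):
            score = composite_score(path, matrix, fits, {"C1": ["g1", "g2"]})
        assert np.isnan(score["s1"])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1.0, 1.0, 1.0, 1.0], [1, 1, 0, 0]) == 0.5

    def test_concordant_pair_counting(self):
        # cases {3, 1}, controls {2, 0}: 3 of 4 pairs concordant
        assert roc_auc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_label_swap_complements(self):
        scores = [3, 1, 2, 0]
        labels = [1, 1, 0, 0]
        swapped = [0, 0, 1, 1]
        assert roc_auc(scores, labels) == pytest.approx(1 - roc_auc(scores, swapped))

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=20, unique=True))
    def test_invariant_under_monotone_transform(self, raw):
        scores = np.asarray(raw) / 20.0
        labels = [i % 2 for i in range(len(scores))]
        transformed = np.exp(scores / 25.0)
        assert roc_auc(scores, labels) == pytest.approx(roc_auc(transformed, labels))


class TestWelchT:
    def test_identical_groups(self):
        t, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_swap_negates_t(self):
        t1, p1 = welch_t([1, 2, 3], [4, 5, 7])
        t2, p2 = welch_t([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_textbook_computation_10v10(self):
        rng = np.random.default_rng(21)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 10)
        vx, vy = x.var(ddof=1) / 10, y.var(ddof=1) / 10
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / 9 + vy**2 / 9)
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), df_hand)
        t, p = welch_t(x, y)
        assert t == pytest.approx(t_hand) and p == pytest.approx(p_hand)

    def test_zero_variance_cases(self):
        assert welch_t([2, 2], [2, 2]) == (0.0, 1.0)
        with pytest.warns(UserWarning, match="clamped"):
            t, p = welch_t([2, 2], [5, 5])
        assert np.isinf(t) and 0 < p < 1e-300

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            welch_t([1], [1, 2])


class TestBhAdjust:
    def test_monotone_and_not_below_raw(self):
        raw = np.array([0.001, 0.01, 0.02, 0.8, 0.04])
        adj = bh_adjust(raw)
        assert (adj >= raw - 1e-15).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestClassificationReport:
    def test_report_fields(self):
        scores = pd.Series([3.0, 2.5, 0.1, 0.2], index=list("abcd"))
        labels = pd.Series(["EAC", "EAC", "NE", "NE"], index=list("abcd"))
        rep = classification_report(scores, labels, "EAC", "NE")
        assert rep.roc_auc == 1.0 and rep.n_case == 2 and rep.n_control == 2
        assert rep.welch_t > 0
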