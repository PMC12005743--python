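"""Accuracy metrics, outlier exclusion and statistical tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phospsych.evaluation import (
    discriminability_matrix,
    exclude_outliers,
    mean_with_exclusion,
    pearson_correlation,
    ranksum_test,
    score_model_records,
    topk_accuracy,
)


def _records_from_probs(probs, true_classes, **extra):
    df = pd.DataFrame(probs, columns=[f"prob_{i}" for i in range(probs.shape[1])])
    df["class_id"] = true_classes
    for k, v in extra.items():
        df[k] = v
    return score_model_records(df)


class TestTopK:
    def test_true_class_ranked_second(self):
        probs = np.array([[0.1, 0.6, 0.3]])
        rec = _records_from_probs(probs, [2], pixels=16, grayscales=2)
        t1 = topk_accuracy(rec, k=1)
        t2 = topk_accuracy(rec, k=2)
        assert t1["mean"].iloc[0] == 0.0
        assert t2["mean"].iloc[0] == 100.0

    def test_all_correct(self):
        probs = np.tile([0.7, 0.1, 0.1, 0.1], (5, 1))
        rec = _records_from_probs(probs, [0] * 5, pixels=16, grayscales=2)
        assert topk_accuracy(rec, k=1)["mean"].iloc[0] == 100.0
        assert topk_accuracy(rec, k=2)["mean"].iloc[0] == 100.0

    def test_uniform_random_sixteen_class_chance_levels(self, rng):
        """10^4 random probability vectors over 16 classes: Top-1 about
        6.25% and Top-2 about 12.5%, within 3 binomial SDs."""
        n = 10_000
        probs = rng.dirichlet(np.ones(16), size=n)
        true = rng.integers(0, 16, n)
        rec = _records_from_probs(probs, true, pixels=16, grayscales=2)
        t1 = topk_accuracy(rec, k=1)["mean"].iloc[0]
        t2 = topk_accuracy(rec, k=2)["mean"].iloc[0]
        sd1 = 100 * np.sqrt(1 / 16 * 15 / 16 / n)
        sd2 = 100 * np.sqrt(2 / 16 * 14 / 16 / n)
        assert abs(t1 - 6.25) < 3 * sd1
        assert abs(t2 - 12.5) < 3 * sd2

    def test_top2_tie_broken_toward_lowest_class(self):
        probs = np.array([[0.4, 0.3, 0.3]])  # classes 1 and 2 tie for 2nd
        rec = _records_from_probs(probs, [1], pixels=16, grayscales=2)
        assert bool(rec["correct_top2"].iloc[0]) is True
        rec2 = _records_from_probs(probs, [2], pixels=16, grayscales=2)
        assert bool(rec2["correct_top2"].iloc[0]) is False

    def test_aggregation_order_invariance(self, rng):
        """Scoring pooled records equals the n-weighted mean of per-cell
        scores."""
        n = 600
        probs = rng.dirichlet(np.ones(4), size=n)
        rec = _records_from_probs(
            probs,
            rng.integers(0, 4, n),
            pixels=rng.choice([16, 32, 64], n),
            grayscales=rng.choice([2, 4, 8], n),
        )
        pooled = topk_accuracy(rec, k=1, by=[])["mean"].iloc[0]
        cells = topk_accuracy(rec, k=1)
        weighted = (cells["mean"] * cells["n"]).sum() / cells["n"].sum()
        assert pooled == pytest.approx(weighted, abs=1e-9)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            topk_accuracy(pd.DataFrame(columns=["correct_top1", "pixels", "grayscales"]))


class TestOutlierExclusion:
    def test_constant_values_unchanged(self):
        assert exclude_outliers([10, 10, 10, 10]).tolist() == [10, 10, 10, 10]

    def test_large_value_within_two_sd_kept(self):
        # mean 20, population SD 40: |100 - 20| = 80 = 2 SD, not beyond it
        vals = exclude_outliers([0, 0, 0, 0, 100])
        assert vals.tolist() == [0, 0, 0, 0, 100]

    def test_clear_outlier_removed(self):
        # mean 1.8, population SD 2.4: |9 - 1.8| = 7.2 > 4.8
        vals = exclude_outliers([1] * 9 + [9])
        assert vals.tolist() == [1] * 9

    def test_single_value_passthrough(self):
        assert exclude_outliers([5.0]).tolist() == [5.0]

    def test_mean_with_exclusion_table(self):
        per_obs = pd.DataFrame(
            {
                "pixels": [16] * 10,
                "grayscales": [2] * 10,
                "mean": [1.0] * 9 + [9.0],
            }
        )
        out = mean_with_exclusion(per_obs)
        assert out["n"].iloc[0] == 9
        assert out["mean"].iloc[0] == pytest.approx(1.0)


def _brute_force_p(a, b, side):
    """Independent oracle: U from pairwise win counts, p by enumerating
    every assignment of pooled values to the two groups."""
    pooled = np.concatenate([a, b])
    na = len(a)

    def u_of(sample_a, sample_b):
        wins = sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in sample_a for y in sample_b
        )
        return wins

    obs = u_of(a, b) if side == "a>b" else u_of(b, a)
    hits, total = 0, 0
    for pick in combinations(range(len(pooled)), na):
        mask = np.zeros(len(pooled), bool)
        mask[list(pick)] = True
        ua = u_of(pooled[mask], pooled[~mask]) if side == "a>b" else u_of(
            pooled[~mask], pooled[mask]
        )
        hits += ua >= obs - 1e-9
        total += 1
    return hits / total


class TestRankSum:
    def test_identical_samples_give_half_u(self):
        a = [1.0, 2.0, 3.0]
        u, _p = ranksum_test(a, a, side="a<b")
        assert u == pytest.approx(len(a) ** 2 / 2)

    def test_textbook_exact_case(self):
        u, p = ranksum_test([1, 2], [3, 4], side="a<b")
        assert p == pytest.approx(1 / 6)

    def test_exact_matches_scipy_on_tie_free_samples(self, rng):
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            _u, p = ranksum_test(a, b, side="a<b")
            ref = stats.mannwhitneyu(a, b, alternative="less", method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("side", ["a<b", "a>b"])
    def test_exact_matches_brute_force_with_ties(self, side, rng):
        """Exhaustive check against an independently coded enumeration for
        every small sample pair, including tied values."""
        cases = [
            ([1, 1, 2], [2, 3]),
            ([0, 0, 0], [0, 1]),
            ([3, 1, 4, 1], [5, 9, 2]),
            ([1, 2], [1, 2]),
        ]
        for _ in range(4):
            na, nb = rng.integers(2, 5, 2)
            cases.append((rng.integers(0, 4, na).tolist(), rng.integers(0, 4, nb).tolist()))
        for a, b in cases:
            _u, p = ranksum_test(a, b, side=side)
            assert p == pytest.approx(_brute_force_p(np.asarray(a, float), np.asarray(b, float), side), abs=1e-12), (a, b)

    def test_normal_approximation_close_to_exact(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 18)
        _u, p_exact = ranksum_test(a, b, side="a<b", exact_limit=200)
        _u, p_norm = ranksum_test(a, b, side="a<b", exact_limit=0)
        assert abs(p_exact - p_norm) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranksum_test([], [1.0])


class TestPearson:
    def test_perfect_positive_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, 2 * x + 3) == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_correlation([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_invariant_under_positive_affine_transforms(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r = pearson_correlation(x, y)
        assert pearson_correlation(3.7 * x + 11, y) == pytest.approx(r, abs=1e-12)
        assert pearson_correlation(x, 0.2 * y - 5) == pytest.approx(r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestDiscriminability:
    def _human_like_records(self, n_classes, conditions, rng):
        rows = []
        for cls in range(n_classes):
            for v, e in conditions:
                rows.append(
                    dict(class_id=cls, viewpoint_deg=v, expression=e,
                         correct_top1=bool(rng.random() < 0.8))
                )
        return pd.DataFrame(rows)

    def test_all_correct_gives_all_100(self):
        df = pd.DataFrame(
            dict(class_id=[0, 0, 1, 1], viewpoint_deg=[0, 0, 0, 0],
                 expression=["joy", "anger", "joy", "anger"], correct_top1=True)
        )
        mat = discriminability_matrix(df)
        assert (mat.to_numpy() == 100.0).all()

    def test_human_design_has_80_cells(self, rng):
        conds = [(0, "neutral"), (0, "joy"), (0, "anger"), (-45, "neutral"), (45, "neutral")]
        mat = discriminability_matrix(self._human_like_records(16, conds, rng))
        assert mat.size == 80

    def test_model_design_has_144_cells(self, rng):
        conds = [(v, e) for v in (-45, 0, 45) for e in ("neutral", "joy", "anger")]
        mat = discriminability_matrix(self._human_like_records(16, conds, rng))
        assert mat.size == 144

    def test_missing_cell_is_nan_not_zero(self):
        df = pd.DataFrame(
            dict(class_id=[0, 1], viewpoint_deg=[0, 0],
                 expression=["joy", "anger"], correct_top1=[True, True])
        )
        mat = discriminability_matrix(df)
        assert np.isnan(mat.loc[0, (0, "anger")])
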