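"""Factor scoring, score ranges with contiguity correction, and the
two-side classification rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beetmsi.scoring import (
    ClassRange,
    classify_pair,
    classify_side,
    derive_class_ranges,
    fit_scoring_model,
    load_scoring,
    ranges_from_stats,
    save_scoring,
    score_seeds,
)

SQRT2 = float(np.sqrt(2.0))


def toy_table(n=40, k=19, seed=0, informative=True):
    """A feature table with a latent damage axis plus noise."""
    rng = np.random.default_rng(seed)
    latent = np.repeat(np.arange(1, 6), n // 5).astype(float)
    cols = {}
    for j in range(k):
        w = 1.0 if (informative and j % 2 == 0) else 0.1
        cols[f"f{j}"] = w * latent + rng.normal(scale=0.5, size=n)
    table = pd.DataFrame(cols)
    table["true_class"] = latent.astype(int)
    return table


class TestFitScoringModel:
    def test_identical_copies_recover_the_variable(self):
        """19 copies of one variable: the score is that variable,
        standardized, with unit variance."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        table = pd.DataFrame({f"f{j}": x for j in range(19)})
        names = tuple(table.columns)
        model = fit_scoring_model(table, feature_names=names)
        scored = score_seeds(model, table)["score"].to_numpy()
        z = (x - x.mean()) / x.std(ddof=1)
        sign = np.sign(np.dot(scored, z))
        np.testing.assert_allclose(scored, sign * z, atol=1e-9)
        assert scored.var(ddof=1) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_calibration_scores_have_unit_variance(self, seed):
        table = toy_table(seed=seed)
        names = tuple(c for c in table.columns if c != "true_class")
        model = fit_scoring_model(table, feature_names=names)
        scores = score_seeds(model, table)["score"]
        assert scores.var(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert scores.mean() == pytest.approx(0.0, abs=1e-9)

    def test_two_feature_table_matches_eigen_oracle(self):
        """2-variable table: closed-form 2×2 eigendecomposition gives
        scores (z1+z2)/sqrt(2(1+ρ)) — match to 1e-9."""
        table = pd.DataFrame(
            {
                "f0": [1.0, 2.0, 3.0, 6.0],
                "f1": [2.0, 1.0, 5.0, 6.0],
                "true_class": [1, 2, 4, 5],
            }
        )
        model = fit_scoring_model(table, feature_names=("f0", "f1"))
        scores = score_seeds(model, table)["score"].to_numpy()

        X = table[["f0", "f1"]].to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        rho = float(np.corrcoef(Z.T)[0, 1])
        assert rho > 0  # leading eigenvector is then (1,1)/sqrt(2)
        expected = Z.sum(axis=1) / np.sqrt(2.0) / np.sqrt(1.0 + rho)
        np.testing.assert_allclose(scores, expected, atol=1e-9)

    def test_sign_convention_class5_above_class1(self):
        table = toy_table(seed=5)
        table[[c for c in table.columns if c != "true_class"]] *= -1
        names = tuple(c for c in table.columns if c != "true_class")
        model = fit_scoring_model(table, feature_names=names)
        scored = score_seeds(model, table)
        scored["true_class"] = table["true_class"].to_numpy()
        g = scored.groupby("true_class")["score"].mean()
        assert g.loc[5] > g.loc[1]

    def test_zero_variance_feature_named_in_error(self):
        table = toy_table()
        table["f3"] = 7.0
        names = tuple(c for c in table.columns if c != "true_class")
        with pytest.raises(ValueError, match="f3"):
            fit_scoring_model(table, feature_names=names)

    def test_fewer_than_two_seeds_raises(self):
        table = toy_table().iloc[:1]
        names = tuple(c for c in table.columns if c != "true_class")
        with pytest.raises(ValueError, match="at least 2"):
            fit_scoring_model(table, feature_names=names)


class TestScoreSeeds:
    @pytest.fixture()
    def fitted(self):
        table = toy_table(seed=2)
        names = tuple(c for c in table.columns if c != "true_class")
        return fit_scoring_model(table, feature_names=names), table, names

    def test_mean_feature_seed_scores_zero(self, fitted):
        model, table, names = fitted
        row = pd.DataFrame([dict(zip(names, model.feature_means))])
        assert score_seeds(model, row)["score"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_batch_independence(self, fitted):
        model, table, names = fitted
        full = score_seeds(model, table)["score"]
        one = score_seeds(model, table.iloc[[7]])["score"]
        assert one.iloc[0] == pytest.approx(full.iloc[7], abs=1e-12)

    def test_missing_and_extra_columns_raise(self, fitted):
        model, table, names = fitted
        with pytest.raises(ValueError, match="missing"):
            score_seeds(model, table.drop(columns=["f0"]))
        bad = table.copy()
        bad["surprise"] = 1.0
        with pytest.raises(ValueError, match="unexpected"):
            score_seeds(model, bad)

    def test_save_load_round_trip(self, fitted, tmp_path):
        model, table, names = fitted
        ranges = [ClassRange(i, float(i), float(i + 1)) for i in range(1, 6)]
        path = save_scoring(model, ranges, tmp_path / "scoring.yaml")
        back_model, back_ranges = load_scoring(path)
        np.testing.assert_allclose(
            back_model.scoring_coefficients, model.scoring_coefficients
        )
        assert back_ranges == ranges


class TestDeriveClassRanges:
    def test_gap_correction_hand_example(self):
        """A {0,2}: mean 1, SD √2 → high = 1+√2.  B {4,6}: provisional low
        4−√2 leaves a gap → corrected B.low = 1+√2."""
        ranges = ranges_from_stats({1: (1.0, SQRT2), 2: (5.0, SQRT2)})
        assert ranges[0].high == pytest.approx(1 + SQRT2)
        assert ranges[1].low == pytest.approx(1 + SQRT2)
        assert ranges[1].high == pytest.approx(5 + SQRT2)

    def test_overlap_correction_hand_example(self):
        """A {0,2} and B {1,3} overlap: B.low becomes A.high = 1+√2."""
        ranges = ranges_from_stats({1: (1.0, SQRT2), 2: (2.0, SQRT2)})
        assert ranges[1].low == pytest.approx(1 + SQRT2)

    def test_requires_all_five_classes(self):
        with pytest.raises(ValueError, match="5 classes"):
            derive_class_ranges([0.0, 1.0], [1, 1])

    def test_requires_two_seeds_per_class(self):
        scores = [0, 0.1, 1, 1.1, 2, 2.1, 3, 3.1, 4]
        classes = [1, 1, 2, 2, 3, 3, 4, 4, 5]
        with pytest.raises(ValueError, match="class 5"):
            derive_class_ranges(scores, classes)

    def test_tied_class_means_raise(self):
        with pytest.raises(ValueError, match="tied"):
            ranges_from_stats({1: (1.0, 0.5), 2: (1.0, 0.5)})

    def test_full_five_class_derivation(self):
        rng = np.random.default_rng(0)
        scores, classes = [], []
        for c in range(1, 6):
            scores.extend(rng.normal(loc=2.0 * c, scale=0.4, size=12))
            classes.extend([c] * 12)
        ranges = derive_class_ranges(scores, classes)
        assert [r.damage_class for r in ranges] == [1, 2, 3, 4, 5]
        for prev, nxt in zip(ranges, ranges[1:]):
            assert nxt.low == pytest.approx(prev.high)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_ranges_always_tile_an_interval(self, seed):
        """Property: corrected ranges are sorted, strictly increasing and
        contiguous for any calibration score set with distinct means."""
        rng = np.random.default_rng(seed)
        mus = np.sort(rng.normal(scale=3.0, size=5))
        scores, classes = [], []
        for c, mu in enumerate(mus, start=1):
            scores.extend(rng.normal(loc=mu, scale=rng.uniform(0.1, 1.0), size=8))
            classes.extend([c] * 8)
        try:
            ranges = derive_class_ranges(scores, classes)
        except ValueError:
            return  # tied/collapsed configurations are rejected, not mangled
        lows = [r.low for r in ranges]
        assert lows == sorted(lows)
        for prev, nxt in zip(ranges, ranges[1:]):
            assert nxt.low == prev.high
            assert prev.low < prev.high


class TestClassifyPair:
    @pytest.fixture()
    def ranges(self):
        return [ClassRange(i, float(i), float(i + 1)) for i in range(1, 6)]

    def test_agreeing_sides(self, ranges):
        assert classify_pair(ranges, 1.5, 1.2) == 1

    def test_severity_max_rule(self, ranges):
        assert classify_pair(ranges, 1.5, 4.5) == 4
        assert classify_pair(ranges, 4.5, 1.5) == 4

    def test_below_lowest_bound_maps_to_first_class(self, ranges):
        assert classify_pair(ranges, -10.0, -10.0) == 1

    def test_above_highest_bound_maps_to_last_class(self, ranges):
        assert classify_pair(ranges, 99.0, 1.5) == 5

    def test_reject_mode_returns_none(self, ranges):
        assert classify_pair(ranges, -10.0, 1.5, extend=False) is None
        assert classify_pair(ranges, 1.5, 2.5, extend=False) == 2

    def test_boundaries_are_half_open(self, ranges):
        assert classify_side(ranges, 2.0) == 2
        assert classify_side(ranges, 6.0) == 5  # last class closed

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.floats(-2, 8), st.floats(-2, 8), st.floats(0, 3)
    )
    def test_monotone_in_side_scores(self, v, d, bump):
        """Raising either side's score never lowers the predicted class."""
        fixed = [ClassRange(i, float(i), float(i + 1)) for i in range(1, 6)]
        base = classify_pair(fixed, v, d)
        assert classify_pair(fixed, v + bump, d) >= base
        assert classify_pair(fixed, v, d + bump) >= base
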