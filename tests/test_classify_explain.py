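import numpy as np
import pandas as pd
import pytest

from mea_netpharm import (
    auc_lower_ci,
    grouped_loocv,
    model_similarity,
    paired_standardize,
    rank_features,
)
from mea_netpharm.classify_explain import compute_split_shap
from _oracles import bootstrap_lower_ci, pearson


def make_table(rng, n_chips=6, n_windows=4, features=("f0", "f1", "f2"), shift=None):
    """Random feature table; `shift` maps feature -> post-drug mean shift."""
    rows = []
    for c in range(n_chips):
        for condition in ("pre_drug", "post_drug"):
            for w in range(n_windows):
                row = {"chip_id": f"chip{c}", "condition": condition, "window_index": w}
                for f in features:
                    value = rng.normal()
                    if shift and condition == "post_drug":
                        value += shift.get(f, 0.0)
                    row[f] = value
                rows.append(row)
    return pd.DataFrame(rows)


class TestPairedStandardize:
    def test_pre_drug_reference_arithmetic(self):
        ft = pd.DataFrame(
            {
                "chip_id": ["c1"] * 6,
                "condition": ["pre_drug"] * 3 + ["post_drug"] * 3,
                "window_index": [0, 1, 2, 0, 1, 2],
                "f": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        out = paired_standardize(ft)
        np.testing.assert_allclose(out["f"], [-1, 0, 1, 2, 3, 4])

    def test_constant_reference_becomes_zero_with_warning(self):
        ft = pd.DataFrame(
            {
                "chip_id": ["c1"] * 4,
                "condition": ["pre_drug", "pre_drug", "post_drug", "post_drug"],
                "window_index": [0, 1, 0, 1],
                "f": [5.0, 5.0, 7.0, 9.0],
            }
        )
        with pytest.warns(UserWarning, match="zero reference SD"):
            out = paired_standardize(ft)
        np.testing.assert_allclose(out["f"], 0.0)

    def test_chips_standardized_independently(self, rng):
        ft = make_table(rng, n_chips=2)
        shifted = ft.copy()
        mask = shifted["chip_id"] == "chip1"
        shifted.loc[mask, ["f0", "f1", "f2"]] += 100.0
        a = paired_standardize(ft)
        b = paired_standardize(shifted)
        other = a["chip_id"] == "chip0"
        pd.testing.assert_frame_equal(a[other], b[other])

    def test_single_reference_window_rejected(self):
        ft = pd.DataFrame(
            {
                "chip_id": ["c9"] * 3,
                "condition": ["pre_drug", "post_drug", "post_drug"],
                "window_index": [0, 0, 1],
                "f": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="c9"):
            paired_standardize(ft)

    def test_pooled_scheme_centers_both_conditions(self, rng):
        ft = make_table(rng, n_chips=2)
        out = paired_standardize(ft, scheme="pooled_per_chip")
        for _, grp in out.groupby("chip_id"):
            assert grp["f0"].mean() == pytest.approx(0.0, abs=1e-12)


class TestGroupedLoocv:
    def test_one_split_per_chip(self, rng):
        ft = make_table(rng, n_chips=9)
        report = grouped_loocv(ft, "nb", seed=0)
        assert len(report.split_aucs) == 9
        assert sorted(report.split_chips) == sorted(ft["chip_id"].unique())

    def test_perfectly_separating_feature_gives_unit_auc(self, rng):
        ft = make_table(rng, n_chips=5)
        ft["f0"] = (ft["condition"] == "post_drug").astype(float)
        report = grouped_loocv(ft, "lr", seed=0)
        np.testing.assert_allclose(report.split_aucs, 1.0)
        assert report.auc_lower_ci == 1.0

    def test_within_chip_label_permutation_null(self, rng):
        ft = make_table(rng, n_chips=6, n_windows=3)
        aucs = []
        for _ in range(50):
            shuffled = ft.copy()
            for _, idx in shuffled.groupby("chip_id").groups.items():
                values = shuffled.loc[idx, "condition"].to_numpy()
                shuffled.loc[idx, "condition"] = rng.permutation(values)
            # permutation can unbalance a chip; skip those draws
            ok = all(
                set(g["condition"]) == {"pre_drug", "post_drug"}
                and min((g["condition"] == "pre_drug").sum(),
                        (g["condition"] == "post_drug").sum()) >= 2
                for _, g in shuffled.groupby("chip_id")
            )
            if not ok:
                continue
            report = grouped_loocv(shuffled, "nb", seed=1)
            aucs.append(report.split_aucs.mean())
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_unknown_model_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown model"):
            grouped_loocv(make_table(rng), "deepnet", seed=0)

    def test_too_few_chips_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 3 chips"):
            grouped_loocv(make_table(rng, n_chips=2), "nb", seed=0)


class TestBootstrapAuc:
    def test_degenerate_distributions(self):
        assert auc_lower_ci([1.0] * 9) == 1.0
        assert auc_lower_ci([0.5] * 9) == 0.5

    def test_matches_independent_oracle(self):
        splits = [0.6, 0.7, 0.8, 0.9, 1.0, 0.6, 0.7, 0.8, 0.9]
        ours = auc_lower_ci(splits, n_boot=1000, seed=0)
        theirs = bootstrap_lower_ci(splits, n_boot=1000, seed=0)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_bounded_by_split_range(self, rng):
        for _ in range(20):
            splits = rng.uniform(0.4, 1.0, size=9)
            value = auc_lower_ci(splits, seed=int(rng.integers(1000)))
            assert splits.min() - 1e-12 <= value <= splits.max() + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            auc_lower_ci([])


class TestRanking:
    def test_single_split_ordering(self):
        shap = [np.array([[0.5, 0.1], [0.5, 0.1]])]
        table = rank_features(shap, ["a", "b"])
        assert list(table["feature"]) == ["a", "b"]
        assert list(table["rank"]) == [1, 2]

    def test_identical_splits_collapse_min_max(self):
        s = np.array([[0.3, 0.6]])
        table = rank_features([s, s, s], ["a", "b"])
        row = table.set_index("feature").loc["b"]
        assert row["min_abs_shap"] == row["max_abs_shap"] == row["median_abs_shap"]

    def test_synchrony_only_effect_ranks_first_for_svm_and_nb(self, rng):
        features = [f"f{i}" for i in range(7)] + ["spike_contrast"]
        ft = make_table(
            rng, n_chips=6, n_windows=4, features=features,
            shift={"spike_contrast": 3.0},
        )
        st = paired_standardize(ft)
        for model in ("svm", "nb"):
            report = grouped_loocv(st, model, seed=2)
            compute_split_shap(report, st, seed=2, n_permutations=32, background_size=8)
            table = rank_features(report.shap_per_split, report.feature_names, st)
            assert table.iloc[0]["feature"] == "spike_contrast"
            assert table.set_index("feature").loc["spike_contrast", "direction"] == 1


class TestModelSimilarity:
    @staticmethod
    def ranking(features, values):
        return pd.DataFrame({"feature": features, "median_abs_shap": values})

    def test_identical_and_opposite_vectors(self):
        feats = ["a", "b", "c"]
        r1 = self.ranking(feats, [0.1, 0.5, 0.9])
        r2 = self.ranking(feats, [0.9, 0.5, 0.1])
        sim = model_similarity({"m1": r1, "m2": r1.copy(), "m3": r2})
        assert sim.loc["m1", "m2"] == pytest.approx(1.0)
        assert sim.loc["m1", "m3"] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(sim.to_numpy()), 1.0)

    def test_matches_handrolled_pearson(self, rng):
        feats = [f"f{i}" for i in range(10)]
        vectors = {f"m{k}": rng.random(10) for k in range(3)}
        sim = model_similarity(
            {name: self.ranking(feats, v) for name, v in vectors.items()}
        )
        assert sim.loc["m0", "m1"] == pytest.approx(
            pearson(vectors["m0"], vectors["m1"]), abs=1e-12
        )
        assert sim.loc["m1", "m2"] == pytest.approx(
            pearson(vectors["m1"], vectors["m2"]), abs=1e-12
        )

    def test_mismatched_feature_sets_rejected(self):
        r1 = self.ranking(["a", "b"], [0.1, 0.2])
        r2 = self.ranking(["a", "c"], [0.1, 0.2])
        with pytest.raises(ValueError, match="mismatched"):
            model_similarity({"m1": r1, "m2": r2})
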