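"""Training protocol, splitting, evaluation and the ablation machinery."""

import numpy as np
import pandas as pd
import pytest

import sgrnet
from sgrnet import (
    EvaluationReport,
    FishDataset,
    InputSetDescriptor,
    NetConfig,
    ValidationError,
    combine_datasets,
)
from sgrnet.io import model_to_json


def _linear_dataset(seed, n=300):
    """SGR an exact linear function of the raw (hence normalized) features."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "weight_g": rng.uniform(10, 50, n),
        "tc_ratio": rng.uniform(1, 8, n),
        "cf": rng.uniform(0.9, 1.5, n),
    })
    df["sgr"] = 2.0 + 0.05 * df.weight_g - 0.2 * df.tc_ratio + 1.0 * df.cf
    return FishDataset(df, label=f"linear{seed}")


class TestInputSets:
    def test_seven_canonical_sets(self):
        assert len(sgrnet.INPUT_SETS) == 7
        sizes = sorted(s.m for s in sgrnet.INPUT_SETS)
        assert sizes == [1, 1, 1, 2, 2, 2, 3]

    @pytest.mark.parametrize("features", [(), ("weight", "weight"), ("fins",)])
    def test_invalid_descriptors_rejected(self, features):
        with pytest.raises(ValidationError):
            InputSetDescriptor(features)


class TestSplit:
    @pytest.mark.parametrize("n, expected_test",
                             [(20, 3), (24, 4), (79, 12), (109, 16), (499, 75)])
    def test_nearest_integer_test_sizes(self, n, expected_test):
        df = pd.DataFrame({"weight_g": np.linspace(1, 2, n),
                           "tc_ratio": 1.0, "cf": 1.0})
        data = FishDataset(df, label="x")
        train, test = sgrnet.split_train_test(data, 0.15, seed=0)
        assert len(test) == expected_test
        assert len(train) == n - expected_test

    def test_partition_is_exact_and_deterministic(self):
        df = pd.DataFrame({"weight_g": np.arange(1.0, 51.0),
                           "tc_ratio": 1.0, "cf": 1.0})
        data = FishDataset(df, label="x")
        tr1, te1 = sgrnet.split_train_test(data, 0.15, seed=7)
        tr2, te2 = sgrnet.split_train_test(data, 0.15, seed=7)
        assert tr1.df.weight_g.tolist() == tr2.df.weight_g.tolist()
        assert te1.df.weight_g.tolist() == te2.df.weight_g.tolist()
        merged = sorted(tr1.df.weight_g.tolist() + te1.df.weight_g.tolist())
        assert merged == data.df.weight_g.tolist()

    def test_combined_dataset_splits_per_constituent(self):
        parts = [
            sgrnet.generate_dataset(sgrnet.PRESETS["juvenile"], n=100, seed=1,
                                    label="p1"),
            sgrnet.generate_dataset(sgrnet.PRESETS["adult"], n=20, seed=2,
                                    label="p2"),
        ]
        combined = combine_datasets(parts)
        train, test = sgrnet.split_train_test(combined, 0.15, seed=0)
        counts = test.df["dataset"].value_counts()
        assert counts["p1"] == 15  # round(100 * 0.15)
        assert counts["p2"] == 3   # round(20 * 0.15)

    def test_too_small_dataset_rejected(self):
        df = pd.DataFrame({"weight_g": [1.0], "tc_ratio": [1.0], "cf": [1.0]})
        with pytest.raises(ValidationError):
            sgrnet.split_train_test(FishDataset(df, label="x"), 0.5, seed=0)


class TestTrainEstimate:
    def test_linear_target_is_learned(self):
        """A target linear in the inputs is recovered to near machine noise
        (cross-checked against the closed-form ridge solution elsewhere)."""
        data = _linear_dataset(seed=0)
        train, test = sgrnet.split_train_test(data, 0.15, seed=0)
        model = sgrnet.train_model(train, sgrnet.INPUT_SETS[-1],
                                   NetConfig(lam=1.0), seed=0)
        rep = sgrnet.evaluate(model, test)
        assert rep.mse < 1e-4

    def test_single_record_rejected(self):
        df = pd.DataFrame({"weight_g": [10.0], "tc_ratio": [2.0],
                           "cf": [1.0], "sgr": [1.0]})
        with pytest.raises(ValidationError):
            sgrnet.train_model(FishDataset(df, label="one"),
                               sgrnet.INPUT_SETS[-1])

    def test_missing_sgr_rejected(self, juvenile_data):
        stripped = FishDataset(juvenile_data.df.drop(columns=["sgr"]),
                               label="nosgr")
        with pytest.raises(ValidationError):
            sgrnet.train_model(stripped, sgrnet.INPUT_SETS[-1])

    def test_training_is_deterministic(self, small_data):
        m1 = sgrnet.train_model(small_data, sgrnet.INPUT_SETS[-1], seed=3)
        m2 = sgrnet.train_model(small_data, sgrnet.INPUT_SETS[-1], seed=3)
        assert model_to_json(m1) == model_to_json(m2)

    def test_ranges_come_from_training_data_only(self, juvenile_data):
        train, _ = sgrnet.split_train_test(juvenile_data, 0.15, seed=11)
        model = sgrnet.train_model(train, sgrnet.INPUT_SETS[-1], seed=11)
        w = train.df["weight_g"]
        assert model.feature_ranges["weight"].min == w.min()
        assert model.feature_ranges["weight"].max == w.max()
        assert model.sgr_range.min == train.df["sgr"].min()

    def test_estimates_on_training_data_track_targets(self, trained_model,
                                                      juvenile_data):
        train, _ = sgrnet.split_train_test(juvenile_data, 0.15, seed=11)
        sgr, y_norm = sgrnet.estimate_sgr(trained_model, train)
        # denormalization is the affine image of the normalized outputs
        lo, hi = trained_model.sgr_range.min, trained_model.sgr_range.max
        expect = lo + (y_norm + 1) * 0.5 * (hi - lo)
        assert np.allclose(sgr, expect, atol=1e-12)
        # and the estimates correlate strongly with the truth
        assert np.corrcoef(sgr, train.sgr_values())[0, 1] > 0.9

    def test_duplicated_records_at_distant_positions_agree(self):
        """The same fish placed at two distant positions gets nearly the
        same estimate: the echo-state property washes out the differing
        record histories, leaving only a small residue from the most recent
        predecessors (well under the noise scale of the data)."""
        data = _linear_dataset(seed=1, n=400)
        df = data.df.copy()
        df.iloc[399] = df.iloc[150]
        dup = FishDataset(df, label="dup")
        model = sgrnet.train_model(dup, sgrnet.INPUT_SETS[-1],
                                   NetConfig(lam=1.0), seed=1)
        sgr, _ = sgrnet.estimate_sgr(model, dup)
        assert abs(sgr[399] - sgr[150]) < 1e-2
        assert abs(sgr[399] - sgr[150]) < 0.01 * abs(sgr[150])

    def test_missing_feature_at_estimation_rejected(self, trained_model):
        df = pd.DataFrame({"weight_g": [20.0], "tc_ratio": [4.0],
                           "cf": [np.nan]})
        with pytest.raises(ValidationError):
            sgrnet.estimate_sgr(trained_model, FishDataset(df, label="x"))

    def test_subset_model_ignores_extra_columns(self, juvenile_data):
        sub = InputSetDescriptor(("weight", "tc_ratio"))
        model = sgrnet.train_model(juvenile_data, sub, seed=0)
        sgr, _ = sgrnet.estimate_sgr(model, juvenile_data)
        assert len(sgr) == len(juvenile_data)
        assert tuple(model.input_set.features) == ("weight", "tc_ratio")


class TestEvaluate:
    def test_hand_computed_mse(self):
        rep = EvaluationReport(
            input_set=sgrnet.INPUT_SETS[-1],
            squared_errors_norm=np.array([0.0, 1.0]),
            squared_errors_real=np.array([0.0, 4.0]),
            predicted_norm=np.array([0.0, 1.0]),
            target_norm=np.array([0.0, 0.0]),
            predicted_sgr=np.array([1.0, 3.0]),
            target_sgr=np.array([1.0, 1.0]),
        )
        assert rep.mse == pytest.approx(0.5)
        assert rep.mse_sd == pytest.approx(0.5)  # population SD of {0, 1}
        assert rep.mse_real == pytest.approx(2.0)

    def test_perfect_predictions_give_zero_mse(self, trained_model):
        train_like = sgrnet.FishDataset(
            pd.DataFrame({"weight_g": [20.0, 25.0], "tc_ratio": [4.0, 5.0],
                          "cf": [1.2, 1.1]}), label="t")
        sgr, _ = sgrnet.estimate_sgr(trained_model, train_like)
        df = train_like.df.assign(sgr=sgr)
        rep = sgrnet.evaluate(trained_model, sgrnet.FishDataset(df, label="t"))
        assert rep.mse == pytest.approx(0.0, abs=1e-20)
        assert rep.mse_sd == pytest.approx(0.0, abs=1e-20)

    def test_mse_invariant_under_pair_permutation(self, trained_model,
                                                  juvenile_data):
        _, test = sgrnet.split_train_test(juvenile_data, 0.15, seed=11)
        rep = sgrnet.evaluate(trained_model, test)
        perm = np.random.default_rng(0).permutation(len(rep.squared_errors_norm))
        assert rep.squared_errors_norm[perm].mean() == pytest.approx(rep.mse)

    def test_empty_test_set_rejected(self, trained_model, juvenile_data):
        empty = juvenile_data.take(np.array([], dtype=int))
        with pytest.raises(ValidationError):
            sgrnet.evaluate(trained_model, empty)


class TestAblation:
    def test_table_shape_and_determinism(self, juvenile_data):
        t1 = sgrnet.ablation_study(juvenile_data, NetConfig(lam=0.3), seed=5)
        t2 = sgrnet.ablation_study(juvenile_data, NetConfig(lam=0.3), seed=5)
        assert len(t1) == 7
        assert t1["inputs"].tolist() == t2["inputs"].tolist()
        assert np.allclose(t1["mse"], t2["mse"])
        assert t1["rank"].tolist() == list(range(1, 8))
        assert t1["is_full_set"].sum() == 1

    def test_tc_only_signal_keeps_tc_model_competitive(self):
        """When SGR depends only on T/C, the {T/C} model is within 2x of the
        three-input model: the extra inputs add no signal."""
        rng = np.random.default_rng(8)
        n = 300
        tc = rng.uniform(1, 8, n)
        df = pd.DataFrame({
            "weight_g": rng.uniform(10, 50, n),
            "tc_ratio": tc,
            "cf": rng.uniform(0.9, 1.5, n),
            "sgr": 1.0 + 0.4 * tc + rng.normal(0, 0.05, n),
        })
        table = sgrnet.ablation_study(FishDataset(df, label="tconly"),
                                      NetConfig(lam=1.0), seed=8)
        t = table.set_index("inputs")["mse"]
        assert t["tc_ratio"] < 2.0 * t["weight+tc_ratio+cf"]


class TestCombine:
    def test_sizes_add_and_labels_kept(self):
        parts = [
            sgrnet.generate_dataset(sgrnet.PRESETS["juvenile"], n=499, seed=0,
                                    label="d1"),
            sgrnet.generate_dataset(sgrnet.PRESETS["post_smolt"], n=24, seed=1,
                                    label="d2"),
            sgrnet.generate_dataset(sgrnet.PRESETS["adult"], n=109, seed=2,
                                    label="d4"),
        ]
        combined = combine_datasets(parts)
        assert len(combined) == 632
        assert combined.parts == ("d1", "d2", "d4")
        assert set(combined.df["dataset"]) == {"d1", "d2", "d4"}

    def test_self_combination_doubles_n_keeps_ranges(self, small_data):
        doubled = combine_datasets([small_data, small_data])
        assert len(doubled) == 2 * len(small_data)
        m1 = sgrnet.train_model(small_data, sgrnet.INPUT_SETS[-1], seed=0)
        m2 = sgrnet.train_model(doubled, sgrnet.INPUT_SETS[-1], seed=0)
        for f in ("weight", "tc_ratio", "cf"):
            assert m1.feature_ranges[f] == m2.feature_ranges[f]
        assert m1.sgr_range == m2.sgr_range

    def test_combined_sgr_range_spans_all_parts(self):
        parts = [
            sgrnet.generate_dataset(sgrnet.PRESETS["juvenile"], n=50, seed=0),
            sgrnet.generate_dataset(sgrnet.PRESETS["adult"], n=50, seed=1),
        ]
        combined = combine_datasets(parts)
        model = sgrnet.train_model(combined, sgrnet.INPUT_SETS[-1], seed=0)
        mins = [p.df["sgr"].min() for p in parts]
        maxs = [p.df["sgr"].max() for p in parts]
        assert model.sgr_range.min == min(mins)
        assert model.sgr_range.max == max(maxs)

    def test_schema_mismatch_rejected(self, small_data):
        no_sgr = FishDataset(small_data.df.drop(columns=["sgr"]), label="n")
        with pytest.raises(ValidationError):
            combine_datasets([small_data, no_sgr])


class TestCrossPopulationRanking:
    def test_two_stage_models_agree_on_population_ranking(self):
        """Models trained on very different stages rank three populations
        with known SGR ordering A > C > B identically (the populations are
        normalized jointly, as one wild dataset)."""
        pops = sgrnet.generate_ranked_populations(seed=3)
        combined = combine_datasets([pops[k] for k in "ABC"])
        labels = combined.df["dataset"].to_numpy()
        orders = []
        for stage in ("juvenile", "adult"):
            train = sgrnet.generate_dataset(sgrnet.PRESETS[stage], seed=1003)
            model = sgrnet.train_model(train, sgrnet.INPUT_SETS[-1],
                                       NetConfig(lam=1.0), seed=3)
            est, _ = sgrnet.estimate_sgr(model, combined, input_ranges="data")
            means = {k: est[labels == f"pop_{k}"].mean() for k in "ABC"}
            orders.append("".join(sorted(means, key=means.get, reverse=True)))
        assert orders[0] == orders[1] == "ACB"
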