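"""MLP training, model-selection protocol, and sample-level calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from cytoshape import classify as clf


def gaussian_table(n=200, separation=4.0, seed=0, d=4):
    rng = np.random.default_rng(seed)
    Xp = rng.normal(0, 1, (n, d))
    Xn = rng.normal(0, 1, (n, d))
    Xp[:, 0] += separation
    cols = [f"f{i}" for i in range(d)]
    df = pd.DataFrame(np.vstack([Xp, Xn]), columns=cols)
    df["cls"] = ["high"] * n + ["low"] * n
    return df, cols


class StubPredictor:
    """Predicts the true class correctly with probability ``p_correct``;
    the table must carry a ``truth`` column of 0/1."""

    def __init__(self, p_correct: float, seed: int = 0):
        self.p = p_correct
        self.rng = np.random.default_rng(seed)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        truth = table["truth"].to_numpy()
        correct = self.rng.random(len(truth)) < self.p
        return np.where(correct, truth, 1 - truth)


class TestPartition:
    def test_fractions_and_exclusivity(self):
        df, _ = gaussian_table(n=100)
        part = clf.partition_data(df, "cls", seed=0)
        assert len(part.train) == 100
        assert len(part.test) == 50
        assert len(part.validation) == 50
        all_idx = np.concatenate([part.train, part.test, part.validation])
        assert sorted(all_idx) == list(range(200))
        assert not (set(part.train) & set(part.test))
        assert not (set(part.train) & set(part.validation))

    def test_stratified_by_class(self):
        df, _ = gaussian_table(n=60)
        part = clf.partition_data(df, "cls", seed=1)
        for idx in (part.train, part.test, part.validation):
            classes = df.loc[idx, "cls"]
            assert (classes == "high").sum() == (classes == "low").sum()

    def test_seeded_determinism(self):
        df, _ = gaussian_table()
        a = clf.partition_data(df, "cls", seed=5)
        b = clf.partition_data(df, "cls", seed=5)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.validation, b.validation)

    def test_small_class_errors(self):
        df, _ = gaussian_table(n=5)
        with pytest.raises(ValueError):
            clf.partition_data(df, "cls")


class TestTraining:
    def test_xor_separates_for_most_seeds(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        y = np.array([0, 1, 1, 0], float)
        solved = 0
        for s in range(20):
            spec = clf.MLPSpec(features=("a", "b"), hidden_units=2, seed=s,
                               max_iter=2000)
            model = clf.train_scg(X, y, spec)
            solved += int((model.predict(X) == y).all())
        assert solved >= 18  # >= 90% of seeds

    def test_separable_gaussians_high_accuracy(self):
        # separation 6 SD: Bayes accuracy Phi(3) ~ 0.9987, so a well-trained
        # net should be essentially perfect on held-out data
        df, cols = gaussian_table(n=150, separation=6.0, seed=3)
        part = clf.partition_data(df, "cls", seed=3)
        spec = clf.MLPSpec(features=tuple(cols), hidden_units=5, seed=3)
        model, acc = clf.final_fit_and_validate(spec, df, "cls", "high", part)
        assert acc >= 0.99

    def test_pure_noise_chance_level(self):
        df, cols = gaussian_table(n=200, separation=0.0, seed=4)
        part = clf.partition_data(df, "cls", seed=4)
        spec = clf.MLPSpec(features=tuple(cols), hidden_units=5, seed=4)
        _, acc = clf.final_fit_and_validate(spec, df, "cls", "high", part)
        assert 0.35 <= acc <= 0.65

    def test_scg_loss_non_increasing(self):
        df, cols = gaussian_table(n=60, separation=2.0, seed=5)
        spec = clf.MLPSpec(features=tuple(cols), hidden_units=5, seed=5,
                           restarts=1)
        model = clf.train_scg(df[cols].to_numpy(),
                              (df["cls"] == "high").to_numpy(float), spec)
        assert (np.diff(model.losses) <= 1e-12).all()

    def test_gd_fallback_agrees_qualitatively(self):
        df, cols = gaussian_table(n=150, separation=4.0, seed=6)
        part = clf.partition_data(df, "cls", seed=6)
        for opt in ("scg", "gd"):
            spec = clf.MLPSpec(features=tuple(cols), hidden_units=5, seed=6,
                               optimizer=opt, max_iter=2000)
            _, acc = clf.final_fit_and_validate(spec, df, "cls", "high", part)
            assert acc >= 0.95, opt

    def test_probabilities_valid(self):
        df, cols = gaussian_table(n=60, seed=7)
        spec = clf.MLPSpec(features=tuple(cols), seed=7)
        model = clf.train_scg(df[cols].to_numpy(),
                              (df["cls"] == "high").to_numpy(float), spec)
        proba = model.predict_proba(df)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert ((proba >= 0) & (proba <= 1)).all()

    def test_missing_feature_errors(self):
        df, cols = gaussian_table(n=30, seed=8)
        spec = clf.MLPSpec(features=tuple(cols), seed=8)
        model = clf.train_scg(df[cols].to_numpy(),
                              (df["cls"] == "high").to_numpy(float), spec)
        with pytest.raises(KeyError):
            model.predict_proba(df.drop(columns=[cols[0]]))

    def test_model_json_round_trip(self, tmp_path):
        df, cols = gaussian_table(n=40, seed=9)
        spec = clf.MLPSpec(features=tuple(cols), seed=9)
        model = clf.train_scg(df[cols].to_numpy(),
                              (df["cls"] == "high").to_numpy(float), spec)
        model.save(tmp_path / "m.json")
        loaded = clf.TrainedModel.load(tmp_path / "m.json")
        assert np.allclose(loaded.predict_proba(df), model.predict_proba(df))


class TestLeakageGuards:
    def test_standardization_uses_training_statistics_only(self):
        df, cols = gaussian_table(n=60, seed=10)
        X = df[cols].to_numpy()
        y = (df["cls"] == "high").to_numpy(float)
        model = clf.train_scg(X, y, clf.MLPSpec(features=tuple(cols), seed=10))
        assert np.allclose(model.feature_mean, X.mean(axis=0))
        # predicting on shifted data must reuse the stored statistics
        shifted = df.copy()
        shifted[cols] += 100.0
        p0 = model.predict_proba(df)[:, 1]
        p1 = model.predict_proba(shifted)[:, 1]
        assert not np.allclose(p0, p1)

    def test_validation_rows_untouched_by_selection_and_fit(self):
        df, cols = gaussian_table(n=100, seed=11)
        part = clf.partition_data(df, "cls", seed=11)
        frozen = df.loc[part.validation].copy()
        cands = clf.candidate_specs(cols, hidden_units=(2, 5), seed=11)
        spec, _ = clf.select_model(cands, df, "cls", "high", part,
                                   n_repartitions=2, seed=11)
        clf.final_fit_and_validate(spec, df, "cls", "high", part)
        pd.testing.assert_frame_equal(df.loc[part.validation], frozen)
        # the final-fit training statistics exclude validation rows
        fit_idx = np.concatenate([part.train, part.test])
        model, _ = clf.final_fit_and_validate(spec, df, "cls", "high", part)
        assert np.allclose(model.feature_mean,
                           df.loc[fit_idx, cols].to_numpy().mean(axis=0))


class TestModelSelection:
    def test_deterministic_from_seed(self):
        df, cols = gaussian_table(n=80, separation=1.0, seed=12)
        part = clf.partition_data(df, "cls", seed=12)
        cands = clf.candidate_specs(cols, hidden_units=(2, 10), seed=12)
        a, sa = clf.select_model(cands, df, "cls", "high", part,
                                 n_repartitions=2, seed=12)
        b, sb = clf.select_model(cands, df, "cls", "high", part,
                                 n_repartitions=2, seed=12)
        assert a.hidden_units == b.hidden_units
        pd.testing.assert_frame_equal(sa, sb)

    def test_added_candidate_does_not_change_other_scores(self):
        df, cols = gaussian_table(n=80, separation=2.0, seed=13)
        part = clf.partition_data(df, "cls", seed=13)
        c1 = clf.candidate_specs(cols, hidden_units=(5,), seed=13)
        c2 = c1 + [clf.MLPSpec(features=(cols[0],), hidden_units=2, seed=13)]
        _, s1 = clf.select_model(c1, df, "cls", "high", part,
                                 n_repartitions=2, seed=13)
        _, s2 = clf.select_model(c2, df, "cls", "high", part,
                                 n_repartitions=2, seed=13)
        assert s1.loc[0, "mean_test_accuracy"] == s2.loc[0, "mean_test_accuracy"]

    def test_separable_data_all_candidates_good(self):
        df, cols = gaussian_table(n=120, separation=4.0, seed=14)
        part = clf.partition_data(df, "cls", seed=14)
        cands = clf.candidate_specs(cols, hidden_units=(2, 5, 10), seed=14)
        spec, scores = clf.select_model(cands, df, "cls", "high", part,
                                        n_repartitions=3, seed=14)
        assert (scores["mean_test_accuracy"] >= 0.95).all()

    def test_greedy_forward_selection_finds_informative_feature(self):
        df, cols = gaussian_table(n=100, separation=3.0, seed=15)
        part = clf.partition_data(df, "cls", seed=15)
        spec = clf.greedy_forward_selection(cols, df, "cls", "high", part,
                                            hidden_units=3, n_repartitions=2,
                                            max_features=2, seed=15)
        assert "f0" in spec.features  # the only informative dimension


class TestClassifySamples:
    def test_perfect_model(self):
        df, cols = gaussian_table(n=100, separation=8.0, seed=16)
        part = clf.partition_data(df, "cls", seed=16)
        spec = clf.MLPSpec(features=tuple(cols), hidden_units=5, seed=16)
        model, acc = clf.final_fit_and_validate(spec, df, "cls", "high", part)
        assert acc == 1.0
        rep = clf.classify_samples(model, df.loc[part.validation], "cls",
                                   "high", seed=16)
        assert rep.tp == 100 and rep.tn == 100
        assert rep.accuracy == 1.0 and rep.fnr == 0.0 and rep.tpr == 1.0

    def test_stub_matches_binomial_oracle(self):
        # exact oracle: P(Bin(10, 0.8) > 6) for class-1 samples
        df = pd.DataFrame({"truth": [1] * 50 + [0] * 50,
                           "cls": ["high"] * 50 + ["low"] * 50})
        stub = StubPredictor(0.8, seed=17)
        rep = clf.classify_samples(stub, df, "cls", "high", n_pairs=3000,
                                   threshold=0.6, seed=17)
        recall = rep.tp / (rep.tp + rep.fn)
        oracle = 1.0 - binom.cdf(6, 10, 0.8)  # ~0.8791
        assert recall == pytest.approx(oracle, abs=0.02)

    def test_p_equal_threshold_called_class_two(self):
        class SixOfTen:
            def predict(self, table):
                out = np.zeros(len(table), dtype=int)
                out[:6] = 1
                return out

        df = pd.DataFrame({"cls": ["high"] * 20 + ["low"] * 20,
                           "x": np.arange(40)})
        rep = clf.classify_samples(SixOfTen(), df, "cls", "high",
                                   n_pairs=50, threshold=0.6, seed=18)
        # P = 0.6 exactly, never strictly greater: everything called class 2
        assert rep.tp == 0 and rep.fp == 0
        assert rep.fn == 50 and rep.tn == 50

    def test_fnr_tpr_identity(self):
        df = pd.DataFrame({"truth": [1] * 30 + [0] * 30,
                           "cls": ["high"] * 30 + ["low"] * 30})
        for p in (0.55, 0.7, 0.9):
            rep = clf.classify_samples(StubPredictor(p, seed=19), df, "cls",
                                       "high", n_pairs=200, seed=19)
            assert rep.fnr + rep.tpr == 1.0
            assert rep.tp + rep.tn + rep.fp + rep.fn == 2 * rep.n_sample_pairs

    def test_seeded_determinism(self):
        df = pd.DataFrame({"truth": [1] * 30 + [0] * 30,
                           "cls": ["high"] * 30 + ["low"] * 30})
        a = clf.classify_samples(StubPredictor(0.7, seed=3), df, "cls",
                                 "high", seed=21)
        b = clf.classify_samples(StubPredictor(0.7, seed=3), df, "cls",
                                 "high", seed=21)
        assert a.as_dict() == b.as_dict()

    def test_pool_too_small_errors(self):
        df = pd.DataFrame({"cls": ["high"] * 5 + ["low"] * 30,
                           "x": np.zeros(35)})
        with pytest.raises(ValueError):
            clf.classify_samples(StubPredictor(0.9), df, "cls", "high")


class TestThresholdSweep:
    def test_call_rate_monotone_in_threshold(self):
        df = pd.DataFrame({"truth": [1] * 40 + [0] * 40,
                           "cls": ["high"] * 40 + ["low"] * 40})
        sweep = clf.threshold_sweep(StubPredictor(0.75, seed=22), df, "cls",
                                    "high", thresholds=(0.5, 0.6, 0.7, 0.8, 0.9),
                                    n_pairs=200, seed=22)
        assert (np.diff(sweep["call_rate"]) <= 0).all()

    def test_includes_default_threshold_row(self):
        # stateless predictor: identical seeded samples give identical calls
        rng = np.random.default_rng(23)
        df = pd.DataFrame({"truth": [1] * 20 + [0] * 20,
                           "cls": ["high"] * 20 + ["low"] * 20,
                           "flip": rng.random(40) > 0.8})

        class Fixed:
            def predict(self, table):
                return (table["truth"].to_numpy()
                        ^ table["flip"].to_numpy()).astype(int)

        sweep = clf.threshold_sweep(Fixed(), df, "cls", "high",
                                    n_pairs=100, seed=23)
        rep = clf.classify_samples(Fixed(), df, "cls", "high", n_pairs=100,
                                   threshold=0.6, seed=23)
        row = sweep.loc[sweep["threshold"] == 0.6].iloc[0]
        assert row["accuracy"] == rep.accuracy
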