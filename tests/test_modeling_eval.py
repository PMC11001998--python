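"""Split schemes, metrics and regime evaluation."""

import numpy as np
import pandas as pd
import pytest

from structpcm import (
    ModelSpec,
    SplitKind,
    SplitScheme,
    evaluate_regime,
    fit,
    predict,
    random_split,
    rmse,
    rve,
    semi_blind_select,
    target_holdout_split,
)
from structpcm.modeling_eval import TargetMetrics, _weighted_overall

FAST_SPEC = ModelSpec(n_trees=20)


class TestMetrics:
    def test_perfect_predictions(self):
        obs = np.array([0.1, 0.5, 0.9])
        assert rmse(obs, obs) == 0.0
        assert rve(obs, obs) == 1.0

    def test_mean_predictor_has_zero_rve(self):
        obs = np.array([0.0, 0.25, 0.5, 1.0])
        pred = np.full_like(obs, obs.mean())
        assert rve(pred, obs) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_predictions(self):
        # obs {0,1}, pred {1,0}: rmse 1, rve 1 - 2/0.5 = -3
        assert rmse([1.0, 0.0], [0.0, 1.0]) == 1.0
        assert rve([1.0, 0.0], [0.0, 1.0]) == -3.0

    def test_zero_observed_variance_undefined(self):
        with pytest.raises(ValueError):
            rve([0.1, 0.2], [0.5, 0.5])

    def test_weighted_overall_matches_hand_computation(self):
        per_target = {
            "A": TargetMetrics(rmse=0.1, rve=0.5, n_test=10),
            "B": TargetMetrics(rmse=0.2, rve=0.0, n_test=30),
            "C": TargetMetrics(rmse=0.3, rve=-0.5, n_test=60),
        }
        overall_rmse, overall_rve = _weighted_overall(per_target)
        assert overall_rmse == pytest.approx((1 + 6 + 18) / 100)
        assert overall_rve == pytest.approx((5 + 0 - 30) / 100)


class TestSplits:
    def test_random_split_is_a_partition(self, small_features):
        ds = small_features.dataset
        train, valid = random_split(ds, 0.8, seed=3)
        assert len(train) + len(valid) == len(ds)
        pairs = set(zip(train.molecule_ids, train.target_ids))
        assert pairs.isdisjoint(zip(valid.molecule_ids, valid.target_ids))
        assert len(train) == round(0.8 * len(ds))

    def test_random_split_deterministic_per_seed(self, small_features):
        ds = small_features.dataset
        a = random_split(ds, seed=5)[0]
        b = random_split(ds, seed=5)[0]
        assert a.molecule_ids == b.molecule_ids

    def test_target_holdout_has_zero_leakage(self, small_features):
        ds = small_features.dataset
        held = sorted(set(ds.target_ids))[:2]
        train, valid = target_holdout_split(ds, held)
        assert set(valid.target_ids) == set(held)
        assert not set(train.target_ids) & set(held)
        counts = pd.Series(ds.target_ids).value_counts()
        assert len(valid) == counts[held].sum()

    def test_absent_holdout_target_rejected(self, small_features):
        with pytest.raises(ValueError):
            target_holdout_split(small_features.dataset, ["NOPE"])


class TestSemiBlindSelect:
    def matrix(self, values, ids):
        return pd.DataFrame(values, index=ids, columns=ids)

    def test_dominant_pair_selected_first(self):
        ids = ["A", "B", "C", "D"]
        m = np.full((4, 4), 0.01)
        np.fill_diagonal(m, 1.0)
        m[0, 1] = m[1, 0] = 0.9
        validation, table = semi_blind_select(self.matrix(m, ids), n_pairs=2)
        assert set(table.iloc[0][["validation_target", "training_partner"]]) \
            == {"A", "B"}
        assert table.iloc[0]["similarity"] == 0.9

    def test_pairs_are_disjoint(self):
        rng = np.random.default_rng(0)
        n = 12
        m = rng.uniform(0, 0.5, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ids = [f"T{i}" for i in range(n)]
        validation, table = semi_blind_select(self.matrix(m, ids), n_pairs=6)
        touched = list(table["validation_target"]) + list(table["training_partner"])
        assert len(set(touched)) == len(touched) == 12
        assert set(validation).isdisjoint(table["training_partner"])

    def test_greedy_top_pair_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        n = 6
        m = rng.uniform(0, 1, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ids = [f"T{i}" for i in range(n)]
        _, table = semi_blind_select(self.matrix(m, ids), n_pairs=3)
        best = max(
            (m[i, j], ids[i], ids[j])
            for i in range(n) for j in range(i + 1, n)
        )
        assert set(table.iloc[0][["validation_target", "training_partner"]]) \
            == {best[1], best[2]}

    def test_member_with_fewer_activities_goes_to_validation(self):
        ids = ["A", "B", "C", "D"]
        m = np.full((4, 4), 0.01)
        np.fill_diagonal(m, 1.0)
        m[0, 1] = m[1, 0] = 0.9
        m[2, 3] = m[3, 2] = 0.8
        _, table = semi_blind_select(
            self.matrix(m, ids), n_pairs=2,
            activity_counts={"A": 100, "B": 50, "C": 10, "D": 90},
        )
        assert list(table["validation_target"]) == ["B", "C"]

    def test_insufficient_targets_rejected(self):
        ids = ["A", "B"]
        m = np.eye(2)
        with pytest.raises(ValueError):
            semi_blind_select(self.matrix(m, ids), n_pairs=2)


class TestFitPredict:
    def test_constant_labels_give_constant_predictions(self, small_features):
        ds = small_features.dataset.subset(np.arange(30))
        ds.y[:] = 0.7
        model = fit(FAST_SPEC, ds, seed=0)
        assert np.allclose(predict(model, ds), 0.7)

    def test_same_seed_identical_predictions(self, small_features):
        ds = small_features.dataset
        train, valid = random_split(ds, seed=1)
        p1 = predict(fit(FAST_SPEC, train, seed=9), valid)
        p2 = predict(fit(FAST_SPEC, train, seed=9), valid)
        assert np.array_equal(p1, p2)

    def test_feature_width_mismatch_rejected(self, small_features):
        ds = small_features.dataset
        model = fit(FAST_SPEC, ds, seed=0, molecule_only=True)
        with pytest.raises(ValueError):
            predict(model, ds, molecule_only=False)


class TestEvaluateRegime:
    def test_baseline_uses_molecule_features_only(self, small_features):
        ds = small_features.dataset
        result = evaluate_regime(
            ds, SplitScheme(SplitKind.BASELINE_PER_TARGET, seed=2), FAST_SPEC
        )
        assert set(result.per_target) == set(ds.target_ids)
        # baseline must be computable from the 2048-bit block alone:
        # refitting one target's model on the molecule block reproduces it
        tgt = sorted(set(ds.target_ids))[0]
        sub = ds.subset(ds.target_index[tgt])
        train, valid = random_split(sub, seed=2)
        model = fit(FAST_SPEC, train, seed=2, molecule_only=True)
        assert model.n_features_in_ == ds.n_mol_bits == 2048

    def test_unified_beats_global_mean_on_planted_signal(self, small_features):
        ds = small_features.dataset
        result = evaluate_regime(
            ds, SplitScheme(SplitKind.UNIFIED_RANDOM, seed=0),
            ModelSpec(n_trees=40), n_repeats=1,
        )
        train, valid = random_split(ds, seed=0)
        mean_rmse = rmse(np.full(len(valid), train.y.mean()), valid.y)
        assert result.overall_rmse < mean_rmse
        assert result.overall_rve > 0.0

    def test_unified_repeats_are_averaged(self, small_features):
        ds = small_features.dataset
        r2 = evaluate_regime(
            ds, SplitScheme(SplitKind.UNIFIED_RANDOM, seed=0), FAST_SPEC,
            n_repeats=2,
        )
        singles = [
            evaluate_regime(
                ds, SplitScheme(SplitKind.UNIFIED_RANDOM, seed=0 + rep),
                FAST_SPEC, n_repeats=1,
            )
            for rep in range(2)
        ]
        assert r2.n_repeats == 2
        assert r2.overall_rmse == pytest.approx(
            np.mean([s.overall_rmse for s in singles])
        )
        assert r2.overall_rve == pytest.approx(
            np.mean([s.overall_rve for s in singles])
        )

    def test_blind_validation_contains_exactly_held_targets(self, small_features):
        ds = small_features.dataset
        held = tuple(sorted(set(ds.target_ids))[:2])
        result = evaluate_regime(
            ds,
            SplitScheme(SplitKind.BLIND_RANDOM_TARGETS, seed=1,
                        held_out_targets=held),
            FAST_SPEC,
        )
        assert set(result.per_target) == set(held)
        counts = pd.Series(ds.target_ids).value_counts()
        assert result.n_test == counts[list(held)].sum()

    def test_scheme_holdout_consistency_enforced(self):
        with pytest.raises(ValueError):
            SplitScheme(SplitKind.BLIND_RANDOM_TARGETS, seed=0)
        with pytest.raises(ValueError):
            SplitScheme(SplitKind.UNIFIED_RANDOM, seed=0,
                        held_out_targets=("T0",))


def test_unified_model_helps_data_poor_targets():
    """Joint modeling transfers signal to targets with few activities."""
    from structpcm import SyntheticConfig, build_features, generate_study

    config = SyntheticConfig(
        n_targets=8, residues_per_target=40, n_molecules=200,
        activities_per_target=120, motif_families=4, seed=23,
    )
    study = generate_study(config)
    # starve two targets down to 25 activities each
    raw = study.raw_activities
    keep = []
    for tgt, group in raw.groupby("target_id", sort=True):
        if tgt in ("T006", "T007"):
            group = group.iloc[:25]
        keep.append(group)
    starved = pd.concat(keep, ignore_index=True)
    features = build_features(
        study.structures, study.molecules, starved, min_activities=20
    )
    ds = features.dataset
    spec = ModelSpec(n_trees=60)
    baseline = evaluate_regime(
        ds, SplitScheme(SplitKind.BASELINE_PER_TARGET, seed=1), spec
    )
    unified = evaluate_regime(
        ds, SplitScheme(SplitKind.UNIFIED_RANDOM, seed=1), spec, n_repeats=1
    )
    poor = ["T006", "T007"]
    base_rve = np.nanmean([baseline.per_target[t].rve for t in poor])
    uni_rve = np.nanmean(
        [unified.per_target[t].rve for t in poor if t in unified.per_target]
    )
    assert uni_rve > base_rve
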