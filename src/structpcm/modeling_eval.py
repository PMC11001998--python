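"""Model fitting, validation regimes and RMSE/RVE evaluation.

Four regimes are implemented:

* **baseline_per_target** — classical single-target QSAR: one random
  forest per target on that target's rows, molecule bits only, 80/20
  split.  The overall statistics are test-size-weighted averages of the
  per-target statistics.
* **unified_random** — one joint model on molecule ⊕ protein features with
  a random 80/20 row split; repeated over fresh splits (default 10) and
  averaged, because the per-target composition of a random validation set
  varies between draws.
* **blind_random_targets** — all rows of a set of held-out targets form
  the validation set; the model never sees any activity of those targets.
* **semi_blind_similar_targets** — blind validation where each held-out
  target has a structurally similar partner (by fingerprint Jaccard) left
  in training.

Metrics: RMSE and RVE, the ratio of variance explained, defined in the
coefficient-of-determination form 1 − SSres/SStot, which is negative for
models worse than predicting the validation mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .feature_assembly import AssembledDataset


class SplitKind(str, Enum):
    BASELINE_PER_TARGET = "baseline_per_target"
    UNIFIED_RANDOM = "unified_random"
    BLIND_RANDOM_TARGETS = "blind_random_targets"
    SEMI_BLIND_SIMILAR_TARGETS = "semi_blind_similar_targets"


@dataclass(frozen=True)
class SplitScheme:
    kind: SplitKind
    seed: int = 0
    train_fraction: float = 0.8
    held_out_targets: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        blind = self.kind in (
            SplitKind.BLIND_RANDOM_TARGETS,
            SplitKind.SEMI_BLIND_SIMILAR_TARGETS,
        )
        if blind and not self.held_out_targets:
            raise ValueError(f"{self.kind.value} requires held_out_targets")
        if not blind and self.held_out_targets:
            raise ValueError(f"{self.kind.value} takes no held_out_targets")


@dataclass(frozen=True)
class ModelSpec:
    """Random forest regressor with the study's fixed hyperparameters."""

    n_trees: int = 200
    max_features: Optional[float] = None  # None = library default

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")

    def build(self, seed: int) -> RandomForestRegressor:
        kwargs = {}
        if self.max_features is not None:
            kwargs["max_features"] = self.max_features
        return RandomForestRegressor(
            n_estimators=self.n_trees, random_state=seed, n_jobs=1, **kwargs
        )


@dataclass
class TargetMetrics:
    rmse: float
    rve: float  # nan when validation labels have zero variance
    n_test: int


@dataclass
class EvalResult:
    scheme: SplitScheme
    per_target: dict[str, TargetMetrics]
    overall_rmse: float
    overall_rve: float
    n_train: int
    n_test: int
    n_repeats: int = 1

    def per_target_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(target_id=t, rmse=m.rmse, rve=m.rve, n_test=m.n_test)
                for t, m in sorted(self.per_target.items())
            ]
        )


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Root mean squared error."""
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def rve(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Ratio of variance explained, 1 − SSres/SStot.

    Equals 1 for perfect predictions, 0 for the constant mean predictor,
    and is negative for models worse than the mean.  Undefined (raises)
    when the observed values have zero variance.
    """
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equal-length and non-empty")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("RVE undefined: observed values have zero variance")
    ss_res = np.sum((obs - pred) ** 2)
    return float(1.0 - ss_res / ss_tot)


def random_split(
    dataset: AssembledDataset, fraction: float = 0.8, seed: int = 0
) -> tuple[AssembledDataset, AssembledDataset]:
    """Random disjoint, exhaustive train/validation partition of the rows."""
    n = len(dataset)
    if n < 5:
        raise ValueError("dataset too small to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fraction * n))
    return dataset.subset(order[:n_train]), dataset.subset(order[n_train:])


def target_holdout_split(
    dataset: AssembledDataset, held_out_targets: Sequence[str]
) -> tuple[AssembledDataset, AssembledDataset]:
    """Move every row of the held-out targets into the validation set."""
    held = set(held_out_targets)
    if not held:
        raise ValueError("held_out_targets must be non-empty")
    present = set(dataset.target_ids)
    absent = held - present
    if absent:
        raise ValueError(f"held-out targets not in dataset: {sorted(absent)}")
    mask = np.array([t in held for t in dataset.target_ids])
    train = dataset.subset(np.flatnonzero(~mask))
    valid = dataset.subset(np.flatnonzero(mask))
    assert not held & set(train.target_ids), "held-out rows leaked into training"
    return train, valid


def semi_blind_select(
    similarity: pd.DataFrame,
    n_pairs: int = 15,
    activity_counts: Optional[Mapping[str, int]] = None,
) -> tuple[list[str], pd.DataFrame]:
    """Pick validation targets as one member of each of the closest pairs.

    Pairs are chosen greedily in descending Jaccard similarity, keeping
    pairs disjoint (a target participates in at most one pair).  From each
    pair, the member with fewer curated activities (if counts are given,
    otherwise the lexicographically later id) goes to validation; its
    partner stays in training.  Returns the validation targets and a
    pairing table (validation_target, training_partner, similarity).
    """
    ids = list(similarity.index)
    if len(ids) < 2 * n_pairs:
        raise ValueError(
            f"need at least {2 * n_pairs} targets for {n_pairs} disjoint pairs"
        )
    pairs = [
        (float(similarity.iat[i, j]), ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used: set[str] = set()
    rows = []
    validation: list[str] = []
    for sim, a, b in pairs:
        if len(rows) == n_pairs:
            break
        if a in used or b in used:
            continue
        used.update((a, b))
        if activity_counts is not None:
            val, partner = sorted(
                (a, b), key=lambda t: (activity_counts.get(t, 0), t)
            )[0], None
            partner = b if val == a else a
        else:
            val, partner = max(a, b), min(a, b)
        validation.append(val)
        rows.append(
            dict(validation_target=val, training_partner=partner,
                 similarity=sim)
        )
    if len(rows) < n_pairs:
        raise ValueError("could not form enough disjoint pairs")
    return validation, pd.DataFrame(rows)


def fit(
    model_spec: ModelSpec, train: AssembledDataset, seed: int = 0,
    molecule_only: bool = False,
) -> RandomForestRegressor:
    """Fit the random forest on a training set (optionally ligand bits only)."""
    if len(train) == 0:
        raise ValueError("empty training set")
    X = train.molecule_block() if molecule_only else train.X
    model = model_spec.build(seed)
    model.fit(X, train.y)
    return model


def predict(
    model: RandomForestRegressor, rows: AssembledDataset,
    molecule_only: bool = False, clip: bool = False,
) -> np.ndarray:
    """Predict spKi for feature rows; raw values unless ``clip`` to [0, 1]."""
    X = rows.molecule_block() if molecule_only else rows.X
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature width {X.shape[1]} != model's {model.n_features_in_}"
        )
    pred = model.predict(X)
    return np.clip(pred, 0.0, 1.0) if clip else pred


def cross_validate_training(
    model_spec: ModelSpec, train: AssembledDataset, n_folds: int = 5,
    seed: int = 0, molecule_only: bool = False,
) -> pd.DataFrame:
    """Informational k-fold CV on the training set (hyperparameters are
    fixed for the study; this reports fold-level RMSE/RVE only)."""
    X = train.molecule_block() if molecule_only else train.X
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(folds.split(X)):
        model = model_spec.build(seed)
        model.fit(X[tr], train.y[tr])
        pred = model.predict(X[te])
        rows.append(
            dict(fold=fold, rmse=rmse(pred, train.y[te]),
                 rve=rve(pred, train.y[te]), n_test=len(te))
        )
    return pd.DataFrame(rows)


def _per_target_metrics(
    valid: AssembledDataset, pred: np.ndarray
) -> dict[str, TargetMetrics]:
    metrics: dict[str, TargetMetrics] = {}
    for tgt, rows in valid.target_index.items():
        obs = valid.y[rows]
        p = pred[rows]
        try:
            target_rve = rve(p, obs)
        except ValueError:
            warnings.warn(
                f"target {tgt}: zero label variance in validation, RVE undefined",
                stacklevel=2,
            )
            target_rve = float("nan")
        metrics[tgt] = TargetMetrics(
            rmse=rmse(p, obs), rve=target_rve, n_test=len(rows)
        )
    return metrics


def _weighted_overall(
    per_target: dict[str, TargetMetrics]
) -> tuple[float, float]:
    """Test-size-weighted averages of per-target RMSE and RVE.

    Targets whose RVE is undefined (zero validation-label variance) keep
    their RMSE weight but are excluded from the RVE average.
    """
    n = np.array([m.n_test for m in per_target.values()], float)
    r = np.array([m.rmse for m in per_target.values()])
    v = np.array([m.rve for m in per_target.values()])
    overall_rmse = float(np.sum(n * r) / np.sum(n))
    ok = ~np.isnan(v)
    overall_rve = (
        float(np.sum(n[ok] * v[ok]) / np.sum(n[ok])) if ok.any() else float("nan")
    )
    return overall_rmse, overall_rve


def evaluate_regime(
    dataset: AssembledDataset,
    scheme: SplitScheme,
    model_spec: ModelSpec = ModelSpec(),
    n_repeats: int = 1,
    clip: bool = False,
) -> EvalResult:
    """Run one validation regime end to end and aggregate its statistics.

    Baseline fits one ligand-only model per target; unified fits a single
    joint model, repeated ``n_repeats`` times over fresh 80/20 splits with
    seeds ``seed+0 … seed+n_repeats−1`` and averaged; blind and semi-blind
    fit a single joint model validated on all rows of the held-out
    targets.  Overall statistics are test-size-weighted averages of the
    per-target statistics.
    """
    if scheme.kind is SplitKind.BASELINE_PER_TARGET:
        per_target: dict[str, TargetMetrics] = {}
        n_train_total = n_test_total = 0
        for i, (tgt, rows) in enumerate(sorted(dataset.target_index.items())):
            sub = dataset.subset(rows)
            train, valid = random_split(
                sub, scheme.train_fraction, seed=scheme.seed + i
            )
            model = fit(model_spec, train, seed=scheme.seed + i,
                        molecule_only=True)
            pred = predict(model, valid, molecule_only=True, clip=clip)
            per_target.update(_per_target_metrics(valid, pred))
            n_train_total += len(train)
            n_test_total += len(valid)
        overall_rmse, overall_rve = _weighted_overall(per_target)
        return EvalResult(scheme, per_target, overall_rmse, overall_rve,
                          n_train_total, n_test_total)

    if scheme.kind is SplitKind.UNIFIED_RANDOM:
        repeat_results = []
        for rep in range(n_repeats):
            train, valid = random_split(
                dataset, scheme.train_fraction, seed=scheme.seed + rep
            )
            model = fit(model_spec, train, seed=scheme.seed + rep)
            pred = predict(model, valid, clip=clip)
            per_target = _per_target_metrics(valid, pred)
            repeat_results.append(
                (per_target, *_weighted_overall(per_target),
                 len(train), len(valid))
            )
        # average per-target metrics over the repeats where the target occurs
        merged: dict[str, list[TargetMetrics]] = {}
        for per_target, *_rest in repeat_results:
            for t, m in per_target.items():
                merged.setdefault(t, []).append(m)
        averaged = {
            t: TargetMetrics(
                rmse=float(np.mean([m.rmse for m in ms])),
                rve=float(np.nanmean([m.rve for m in ms]))
                if any(not np.isnan(m.rve) for m in ms) else float("nan"),
                n_test=int(round(np.mean([m.n_test for m in ms]))),
            )
            for t, ms in merged.items()
        }
        return EvalResult(
            scheme,
            averaged,
            overall_rmse=float(np.mean([r[1] for r in repeat_results])),
            overall_rve=float(np.mean([r[2] for r in repeat_results])),
            n_train=int(np.mean([r[3] for r in repeat_results])),
            n_test=int(np.mean([r[4] for r in repeat_results])),
            n_repeats=n_repeats,
        )

    # blind / semi-blind: single joint model, held-out-target validation
    train, valid = target_holdout_split(dataset, scheme.held_out_targets)
    model = fit(model_spec, train, seed=scheme.seed)
    pred = predict(model, valid, clip=clip)
    per_target = _per_target_metrics(valid, pred)
    overall_rmse, overall_rve = _weighted_overall(per_target)
    return EvalResult(scheme, per_target, overall_rmse, overall_rve,
                      len(train), len(valid))
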