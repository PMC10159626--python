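"""Decoding the training condition from neural-activity features.

Trial-resolved activity of one or more neurons, binned and z-normalized, is
fed to standard classifiers (k-nearest-neighbors with k=2 and
distance-weighted votes, a 500-tree random forest, or a two-layer MLP with
50 and 100 units) to predict which training group an animal came from.
Performance is the macro F1 score (unweighted mean of per-class F1) averaged
over 10 rounds of stratified 60/40 train/test splits, with a row-normalized
confusion matrix pooled over rounds.  Three split schemes control what the
classifier may share between train and test: individual trials, trial halves
within an animal, or whole animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .datamodel import StimulusSchedule, TraceRecord
from .traces import (
    NormalizedTrace,
    bin_and_znorm,
    detect_ground_state,
    normalize,
    resample_linear,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DecodingConfig",
    "DecodingResult",
    "FeatureSet",
    "macro_f1",
    "assemble_features",
    "evaluate",
    "neuron_scaling_curve",
]


@dataclass
class DecodingConfig:
    classifier: str = "knn"  # knn | random_forest | mlp
    knn_k: int = 2
    rf_trees: int = 500
    mlp_layers: tuple[int, int] = (50, 100)
    split_scheme: str = "trial"  # trial | within_individual | between_individual
    train_fraction: float = 0.6
    cv_rounds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.classifier not in ("knn", "random_forest", "mlp"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.split_scheme not in ("trial", "within_individual", "between_individual"):
            raise ValueError(f"unknown split_scheme {self.split_scheme!r}")


@dataclass
class DecodingResult:
    macro_f1_mean: float
    macro_f1_sd: float
    per_round_f1: np.ndarray
    per_class_f1: dict[str, float]
    confusion: pd.DataFrame  # row-normalized, rows = true class
    neuron_set: tuple[str, ...]


@dataclass
class FeatureSet:
    """Per-(animal, trial) feature rows ready for classification."""

    X: np.ndarray  # (n_rows, n_neurons * bins_per_trial)
    y: np.ndarray  # group labels (str)
    animals: np.ndarray
    trials: np.ndarray
    neuron_set: tuple[str, ...]


def macro_f1(y_true: Sequence, y_pred: Sequence, classes: Sequence | None = None) -> float:
    """Unweighted mean of per-class F1 scores; zero-division counts as 0."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    scores = []
    for c in classes:
        tp = np.sum((y_true == c) & (y_pred == c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        denom = 2 * tp + fp + fn
        scores.append(2 * tp / denom if denom > 0 else 0.0)
    return float(np.mean(scores))


def assemble_features(
    records: Sequence[TraceRecord],
    neuron_set: Sequence[str],
    schedule: StimulusSchedule,
    bin_frames: int = 20,
    trial_window_s: float | None = None,
) -> FeatureSet:
    """Build per-(animal, trial) feature rows from raw trace records.

    Each record is ground-state normalized (F/F_G), resampled to the highest
    frame rate in the dataset, sliced into the six post-switch trial windows,
    and each slice binned into ``bin_frames``-frame means and z-normalized.
    A row concatenates the per-neuron binned vectors for one (animal, trial)
    and is z-normalized as a whole — normalizing after concatenation keeps
    the between-neuron amplitude ratios that carry the group signal, while a
    common fluorescence scale still cancels.  Animals missing any neuron in
    ``neuron_set`` are dropped with a warning.
    """
    neuron_set = tuple(neuron_set)
    wanted = [r for r in records if r.neuron_id in neuron_set]
    if not wanted:
        raise ValueError("no records match the requested neuron set")
    normed = [
        normalize(
            r.intensity, r.time, "ground_state",
            F_G=detect_ground_state(r.intensity),
            neuron_id=r.neuron_id, animal_id=r.animal_id,
        )
        for r in wanted
    ]
    target_rate = max(r.frame_rate for r in wanted)
    normed = resample_linear(normed, target_rate)
    group_of = {r.animal_id: r.group.short for r in wanted}
    by_animal: dict[str, dict[str, NormalizedTrace]] = {}
    for tr in normed:
        by_animal.setdefault(tr.animal_id, {})[tr.neuron_id] = tr

    switches = schedule.switch_times
    if trial_window_s is None:
        trial_window_s = float(np.min(np.diff(np.append(switches, schedule.end))))

    rows, labels, animals, trials = [], [], [], []
    for animal in sorted(by_animal):
        traces = by_animal[animal]
        if any(nm not in traces for nm in neuron_set):
            logger.warning("animal %s missing neurons; dropped", animal)
            continue
        for trial_i, sw in enumerate(switches):
            feats = []
            ok = True
            for nm in neuron_set:
                tr = traces[nm]
                mask = (tr.time >= sw) & (tr.time < sw + trial_window_s)
                vals = tr.values[mask]
                if vals.size < bin_frames:
                    ok = False
                    break
                feats.append(vals[: (vals.size // bin_frames) * bin_frames])
            if not ok:
                continue
            rows.append(bin_and_znorm(np.concatenate(feats), bin_frames))
            labels.append(group_of[animal])
            animals.append(animal)
            trials.append(trial_i)
    if not rows:
        raise ValueError("feature assembly produced no rows")
    return FeatureSet(
        X=np.asarray(rows),
        y=np.asarray(labels),
        animals=np.asarray(animals),
        trials=np.asarray(trials),
        neuron_set=neuron_set,
    )


def _make_classifier(config: DecodingConfig, random_state: int):
    if config.classifier == "knn":
        return KNeighborsClassifier(n_neighbors=config.knn_k, weights="distance")
    if config.classifier == "random_forest":
        return RandomForestClassifier(
            n_estimators=config.rf_trees, random_state=random_state
        )
    return MLPClassifier(
        hidden_layer_sizes=tuple(config.mlp_layers),
        max_iter=2000,
        random_state=random_state,
    )


def _stratified_split(rng, strata: np.ndarray, train_fraction: float):
    """Index split with every stratum represented on both sides."""
    train_idx, test_idx = [], []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.array(train_idx), np.array(test_idx)


def _round_data(features: FeatureSet, config: DecodingConfig, rng):
    """One cross-validation round's train/test arrays under the split scheme."""
    X, y = features.X, features.y
    if config.split_scheme == "trial":
        tr, te = _stratified_split(rng, y, config.train_fraction)
        return X[tr], y[tr], X[te], y[te]
    if config.split_scheme == "within_individual":
        Xtr, ytr, Xte, yte = [], [], [], []
        for animal in np.unique(features.animals):
            idx = np.flatnonzero(features.animals == animal)
            idx = rng.permutation(idx)
            half = idx.size // 2
            if half == 0:
                continue
            Xtr.append(X[idx[:half]].mean(axis=0))
            ytr.append(y[idx[0]])
            Xte.append(X[idx[half:]].mean(axis=0))
            yte.append(y[idx[0]])
        return np.asarray(Xtr), np.asarray(ytr), np.asarray(Xte), np.asarray(yte)
    # between_individual: trial-average per animal, split by animal id
    animals = np.unique(features.animals)
    Xa, ya = [], []
    for animal in animals:
        idx = np.flatnonzero(features.animals == animal)
        Xa.append(X[idx].mean(axis=0))
        ya.append(y[idx[0]])
    Xa, ya = np.asarray(Xa), np.asarray(ya)
    tr, te = _stratified_split(rng, ya, config.train_fraction)
    return Xa[tr], ya[tr], Xa[te], ya[te]


def evaluate(
    features: FeatureSet, config: DecodingConfig, scrambled: bool = False
) -> DecodingResult:
    """Mean/SD macro F1 over ``cv_rounds`` splits plus the pooled confusion.

    ``scrambled=True`` permutes the class labels before splitting — the
    chance-level control (expected macro F1 ≈ 1/K for K balanced classes).
    """
    classes = np.unique(features.y)
    if classes.size < 2:
        raise ValueError("decoding needs at least 2 classes")
    rng = np.random.default_rng(config.seed)
    y_all = features.y
    if scrambled:
        y_all = rng.permutation(y_all)
        features = FeatureSet(
            X=features.X, y=y_all, animals=features.animals,
            trials=features.trials, neuron_set=features.neuron_set,
        )
    f1s = []
    pooled = pd.DataFrame(0.0, index=classes, columns=classes)
    per_class_acc = {c: [] for c in classes}
    for round_i in range(config.cv_rounds):
        Xtr, ytr, Xte, yte = _round_data(features, config, rng)
        clf = _make_classifier(config, random_state=int(rng.integers(2**31 - 1)))
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        f1s.append(macro_f1(yte, pred, classes))
        for c in classes:
            tp = np.sum((yte == c) & (pred == c))
            fp = np.sum((yte != c) & (pred == c))
            fn = np.sum((yte == c) & (pred != c))
            denom = 2 * tp + fp + fn
            per_class_acc[c].append(2 * tp / denom if denom > 0 else 0.0)
        for t, p in zip(yte, pred):
            pooled.loc[t, p] += 1
    row_sums = pooled.sum(axis=1)
    confusion = pooled.div(row_sums.replace(0, np.nan), axis=0)
    f1s = np.asarray(f1s)
    return DecodingResult(
        macro_f1_mean=float(f1s.mean()),
        macro_f1_sd=float(f1s.std(ddof=1)) if f1s.size > 1 else 0.0,
        per_round_f1=f1s,
        per_class_f1={c: float(np.mean(v)) for c, v in per_class_acc.items()},
        confusion=confusion,
        neuron_set=features.neuron_set,
    )


def neuron_scaling_curve(
    records: Sequence[TraceRecord],
    schedule: StimulusSchedule,
    neuron_sets: Sequence[Sequence[str]],
    config: DecodingConfig,
    include_scrambled: bool = True,
) -> pd.DataFrame:
    """Macro F1 as a function of the number of neurons in the feature set.

    One :func:`evaluate` per neuron set (plus, optionally, a scrambled-label
    control per set).  With informative neurons spread over the sets the
    curve grows with set size while the scrambled curve stays at chance.
    """
    rows = []
    for nset in neuron_sets:
        nset = tuple(nset)
        if not nset:
            raise ValueError("empty neuron set")
        feats = assemble_features(records, nset, schedule)
        res = evaluate(feats, config)
        row = dict(
            n_neurons=len(nset),
            neuron_set=",".join(nset),
            f1_mean=res.macro_f1_mean,
            f1_sd=res.macro_f1_sd,
        )
        if include_scrambled:
            sres = evaluate(feats, config, scrambled=True)
            row["f1_scrambled_mean"] = sres.macro_f1_mean
            row["f1_scrambled_sd"] = sres.macro_f1_sd
        rows.append(row)
    return pd.DataFrame(rows)
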