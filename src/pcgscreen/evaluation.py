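"""Metrics and the two subject-level nested cross-validation protocols.

A screening tool deployed in the field sees far more healthy subjects than
diseased ones, so besides ordinary stratified nested 10-fold CV this module
implements a prevalence-controlled protocol: one outer fold per RHD
subject (leave-one-RHD-subject-out), each evaluation fold holding that one
RHD subject plus ``round(1/p)`` healthy controls drawn from an outer HC
pool, with hyperparameters selected on inner folds built the same way from
a disjoint inner HC pool. HC subjects may be reused across folds (the HC
pool is smaller than the number of fold slots) but never within a fold,
and no subject ever appears on both sides of a train/test split.

Metrics use RHD as the positive class throughout: precision = Tp/(Tp+Fp),
recall = Tp/(Tp+Fn), f1 = their harmonic mean, specificity = Tn/(Tn+Fp).
Each experiment is repeated (five times by default) with fresh fold
randomization, and results are reported as mean +/- standard deviation
over the repeats.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifier import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    Hyperparameters,
    NEGATIVE,
    POSITIVE,
    grid_search,
    predict_raw,
    train_classifier,
)
from .errors import InvalidConfigError, InvalidInputError, LeakageError
from .features.basic import FEATURE_NAMES

METRIC_NAMES = ("f1", "recall", "precision", "specificity")

PROTOCOL_STRATIFIED = "stratified_10fold"
PROTOCOL_IMBALANCED = "imbalanced"


@dataclass(frozen=True)
class ConfusionCounts:
    """Tp/Fp/Fn/Tn with RHD as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Precision, recall, f1 and specificity as fractions in [0, 1].

    A metric whose denominator is zero is reported as 0 and its name is
    listed in ``undefined`` (with a warning at computation time).
    """

    precision: float
    recall: float
    f1: float
    specificity: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in METRIC_NAMES}


def labels_to_int(labels: Sequence) -> np.ndarray:
    """Map RHD/HC string labels to +1/-1; integer labels pass through."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    mapping = {"RHD": POSITIVE, "HC": NEGATIVE}
    try:
        return np.array([mapping[str(v)] for v in arr], dtype=int)
    except KeyError as e:  # pragma: no cover
        raise InvalidInputError(f"unknown label {e.args[0]!r}") from e


def confusion(y_true: Sequence, y_pred: Sequence) -> ConfusionCounts:
    """Exact confusion counts; RHD (+1) is the positive class."""
    yt = labels_to_int(y_true)
    yp = labels_to_int(y_pred)
    if yt.shape != yp.shape:
        raise InvalidInputError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        tp=int(np.sum((yt == POSITIVE) & (yp == POSITIVE))),
        fp=int(np.sum((yt == NEGATIVE) & (yp == POSITIVE))),
        fn=int(np.sum((yt == POSITIVE) & (yp == NEGATIVE))),
        tn=int(np.sum((yt == NEGATIVE) & (yp == NEGATIVE))),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """The four evaluation metrics from confusion counts."""
    undefined: list[str] = []

    def safe(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=2)
            return 0.0
        return num / den

    precision = safe(c.tp, c.tp + c.fp, "precision")
    recall = safe(c.tp, c.tp + c.fn, "recall")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        undefined.append("f1")
        f1 = 0.0
    specificity = safe(c.tn, c.tn + c.fp, "specificity")
    return MetricSet(
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        undefined=tuple(undefined),
    )


def hc_count_for_prevalence(p: float) -> int:
    """Healthy controls per single-RHD evaluation fold: round(1/p).

    Prevalence is read as the RHD:HC ratio of one fold, matching the
    protocol's anchors of 20 HCs at 5% and 40 HCs at 2.5%.
    """
    if not (0.0 < p <= 0.5):
        raise InvalidConfigError(f"prevalence must be in (0, 0.5], got {p}")
    return int(round(1.0 / p))


@dataclass(frozen=True)
class Fold:
    """One train/test split at subject level, with optional nested folds."""

    train: tuple[str, ...]
    test: tuple[str, ...]
    inner: tuple["Fold", ...] = ()


@dataclass(frozen=True)
class FoldPlan:
    """A fully materialized nested partitioning for one repeat."""

    protocol: str
    outer_folds: tuple[Fold, ...]
    repeat_seed: int
    prevalence: float | None = None


def validate_no_leakage(plan: FoldPlan) -> None:
    """Assert subject-level train/test separation in every fold of the plan.

    Also checks that each fold's test set has no duplicated subject and
    that inner folds only ever touch outer-training subjects.
    """
    for k, fold in enumerate(plan.outer_folds):
        train, test = set(fold.train), set(fold.test)
        if len(test) != len(fold.test):
            raise LeakageError(f"outer fold {k}: duplicated subject inside the test set")
        if train & test:
            raise LeakageError(f"outer fold {k}: {train & test} in both train and test")
        for j, inner in enumerate(fold.inner):
            itrain, itest = set(inner.train), set(inner.test)
            if itrain & itest:
                raise LeakageError(f"outer fold {k}, inner {j}: train/test overlap")
            if (itrain | itest) - train:
                raise LeakageError(
                    f"outer fold {k}, inner {j}: inner fold touches outer test subjects"
                )


def imbalanced_fold_plan(
    subjects: Sequence[tuple[str, str]], prevalence: float, seed: int
) -> FoldPlan:
    """Prevalence-controlled leave-one-RHD-subject-out nested plan.

    The HC pool is split once (per repeat) into an inner and an outer pool
    of roughly equal size; every evaluation fold holds 1 RHD subject plus
    ``hc_count_for_prevalence(p)`` HCs sampled without replacement from the
    matching pool. With n RHD subjects the plan has n outer folds and n-1
    inner folds per outer fold. Fully deterministic given ``seed``.
    """
    m = hc_count_for_prevalence(prevalence)
    rhd = [sid for sid, lab in subjects if lab == "RHD"]
    hc = [sid for sid, lab in subjects if lab == "HC"]
    n = len(rhd)
    if n < 2:
        raise InvalidConfigError("imbalanced protocol needs at least 2 RHD subjects")
    rng = np.random.default_rng(seed)
    hc_shuffled = list(rng.permutation(hc))
    # Pools sized by the (n-1):n ratio of inner to outer folds -- near 50/50.
    n_inner_pool = int(round(len(hc) * (n - 1) / (2 * n - 1)))
    inner_pool = hc_shuffled[:n_inner_pool]
    outer_pool = hc_shuffled[n_inner_pool:]
    if len(inner_pool) < m or len(outer_pool) < m:
        raise InvalidConfigError(
            f"need >= {m} HC subjects in each pool for prevalence {prevalence}; "
            f"have {len(inner_pool)} inner / {len(outer_pool)} outer"
        )
    outer_folds = []
    for held_out in rhd:
        train_rhd = [s for s in rhd if s != held_out]
        outer_test_hc = list(rng.choice(outer_pool, size=m, replace=False))
        inner_folds = []
        for inner_held in train_rhd:
            inner_test_hc = list(rng.choice(inner_pool, size=m, replace=False))
            inner_folds.append(
                Fold(
                    train=tuple(
                        [s for s in train_rhd if s != inner_held]
                        + [s for s in inner_pool if s not in set(inner_test_hc)]
                    ),
                    test=tuple([inner_held] + inner_test_hc),
                )
            )
        outer_folds.append(
            Fold(
                train=tuple(train_rhd + inner_pool),
                test=tuple([held_out] + outer_test_hc),
                inner=tuple(inner_folds),
            )
        )
    plan = FoldPlan(
        protocol=PROTOCOL_IMBALANCED,
        outer_folds=tuple(outer_folds),
        repeat_seed=seed,
        prevalence=prevalence,
    )
    validate_no_leakage(plan)
    return plan


def stratified_fold_plan(
    subjects: Sequence[tuple[str, str]], k: int = 10, seed: int = 0
) -> FoldPlan:
    """Stratified nested k-fold plan (outer and inner loops both k-fold).

    Outer folds partition all subjects preserving class proportions within
    one subject; each outer training set is again stratified k-fold split
    for the inner hyperparameter search.
    """
    ids = np.array([sid for sid, _ in subjects])
    labs = np.array([lab for _, lab in subjects])
    for cls in ("RHD", "HC"):
        if int(np.sum(labs == cls)) < k:
            raise InvalidConfigError(
                f"class {cls} has {int(np.sum(labs == cls))} subjects; needs >= k = {k}"
            )
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
    outer_folds = []
    for f, (train_idx, test_idx) in enumerate(outer.split(ids, labs)):
        inner = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + f + 1) % 2**32)
        inner_folds = tuple(
            Fold(train=tuple(ids[train_idx][itr]), test=tuple(ids[train_idx][ite]))
            for itr, ite in inner.split(ids[train_idx], labs[train_idx])
        )
        outer_folds.append(
            Fold(train=tuple(ids[train_idx]), test=tuple(ids[test_idx]), inner=inner_folds)
        )
    plan = FoldPlan(
        protocol=PROTOCOL_STRATIFIED, outer_folds=tuple(outer_folds), repeat_seed=seed
    )
    validate_no_leakage(plan)
    return plan


@dataclass(frozen=True)
class RepeatResult:
    """Pooled predictions and metrics of one nested-CV repeat."""

    metrics: MetricSet
    counts: ConfusionCounts
    selected: tuple[Hyperparameters, ...]  # per outer fold
    seed: int


@dataclass(frozen=True)
class CVReport:
    """Per-repeat metric sets and their mean +/- std (percent)."""

    protocol: str
    prevalence: float | None
    repeats: tuple[RepeatResult, ...]

    def mean_std(self) -> dict[str, tuple[float, float]]:
        """Per metric: (mean, sample std) over repeats, in percent."""
        out = {}
        for name in METRIC_NAMES:
            vals = np.array([getattr(r.metrics, name) for r in self.repeats]) * 100.0
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            out[name] = (float(np.mean(vals)), sd)
        return out

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "prevalence": self.prevalence,
            "n_repeats": len(self.repeats),
            "mean_std_percent": {
                k: {"mean": m, "std": s} for k, (m, s) in self.mean_std().items()
            },
            "repeats": [
                {
                    "seed": r.seed,
                    "metrics_percent": {
                        k: 100.0 * v for k, v in r.metrics.as_dict().items()
                    },
                    "counts": {
                        "tp": r.counts.tp, "fp": r.counts.fp,
                        "fn": r.counts.fn, "tn": r.counts.tn,
                    },
                    "selected_hyperparameters": [
                        {"C": hp.C, "gamma": hp.gamma} for hp in r.selected
                    ],
                }
                for r in self.repeats
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_table(self) -> str:
        """Human-readable table: metric rows, one column per protocol run."""
        header = (
            f"{self.prevalence:.1%}" if self.prevalence is not None else "Stratified 10-Fold"
        )
        lines = [f"{'Parameter':<14}{header:>22}"]
        for name, (m, s) in self.mean_std().items():
            lines.append(f"{name:<14}{m:>14.1f} ± {s:<4.1f}")
        return "\n".join(lines)

    def save(self, directory: str | Path, stem: str = "cv_report") -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        json_path = directory / f"{stem}.json"
        json_path.write_text(self.to_json())
        (directory / f"{stem}.txt").write_text(self.to_table() + "\n")
        return json_path


def _feature_matrix(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, dict[str, int], list[str]]:
    if "subject_id" not in features.columns or "label" not in features.columns:
        raise InvalidInputError("feature table needs subject_id and label columns")
    names = [c for c in features.columns if c not in ("subject_id", "label")]
    X = features[names].to_numpy(dtype=np.float64)
    y = labels_to_int(features["label"].to_numpy())
    index = {sid: i for i, sid in enumerate(features["subject_id"])}
    if len(index) != len(features):
        raise InvalidInputError("duplicate subject_id in feature table")
    return X, y, index, names


def run_nested_cv(
    plan: FoldPlan,
    features: pd.DataFrame,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> RepeatResult:
    """Execute one materialized plan on a feature table.

    Per outer fold: grid-search (C, gamma) on the inner folds, refit on the
    full outer training partition with the winner, predict the outer test
    set. All outer predictions of the repeat are pooled into one MetricSet.
    The plan is leakage-audited before any model sees data.
    """
    validate_no_leakage(plan)
    X, y, index, names = _feature_matrix(features)
    missing = {
        s
        for fold in plan.outer_folds
        for s in (*fold.train, *fold.test)
        if s not in index
    }
    if missing:
        raise InvalidInputError(f"plan references subjects without features: {sorted(missing)[:5]}...")

    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    selected: list[Hyperparameters] = []
    for fold in plan.outer_folds:
        inner_idx = [
            (
                np.array([index[s] for s in inner.train], dtype=int),
                np.array([index[s] for s in inner.test], dtype=int),
            )
            for inner in fold.inner
        ]
        hp = grid_search(inner_idx, X, y, c_grid=c_grid, gamma_grid=gamma_grid)
        selected.append(hp)
        train_idx = np.array([index[s] for s in fold.train], dtype=int)
        test_idx = np.array([index[s] for s in fold.test], dtype=int)
        model = train_classifier(X[train_idx], y[train_idx], hp, feature_names=names)
        pooled_true.append(y[test_idx])
        pooled_pred.append(predict_raw(model, X[test_idx]))
    counts = confusion(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    return RepeatResult(
        metrics=metrics(counts), counts=counts, selected=tuple(selected), seed=plan.repeat_seed
    )


def run_experiment(
    features: pd.DataFrame,
    protocol: str,
    prevalence: float | None = None,
    repeats: int = 5,
    seed: int = 0,
    k: int = 10,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> CVReport:
    """Run a full repeated nested-CV experiment and report mean +/- std.

    ``protocol`` is ``stratified_10fold`` (needs no prevalence) or
    ``imbalanced`` (needs one). Repeat r uses seed ``seed + 1000 * r`` for
    its fold randomization; all seeds are recorded in the report.
    """
    if protocol == PROTOCOL_IMBALANCED and prevalence is None:
        raise InvalidConfigError("imbalanced protocol requires a prevalence")
    if protocol == PROTOCOL_STRATIFIED and prevalence is not None:
        raise InvalidConfigError("stratified protocol does not take a prevalence")
    if protocol not in (PROTOCOL_STRATIFIED, PROTOCOL_IMBALANCED):
        raise InvalidConfigError(f"unknown protocol {protocol!r}")
    subjects = list(zip(features["subject_id"], features["label"]))
    results = []
    for r in range(repeats):
        rep_seed = (seed + 1000 * r) % 2**31
        if protocol == PROTOCOL_IMBALANCED:
            plan = imbalanced_fold_plan(subjects, prevalence, rep_seed)
        else:
            plan = stratified_fold_plan(subjects, k=k, seed=rep_seed)
        results.append(run_nested_cv(plan, features, c_grid=c_grid, gamma_grid=gamma_grid))
    return CVReport(protocol=protocol, prevalence=prevalence, repeats=tuple(results))
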