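"""Subject-wise random-forest training/evaluation and the 3-stage search.

The evaluation protocol is a subject-wise multi-hold-out: the windows of a
training subject never appear in the test set, so performance reflects
generalization to unseen people rather than to unseen windows of the same
person. One evaluation round trains ``n_assignments x n_random_states``
forests (5 x 20 = 100 by default) and aggregates their test accuracies,
row-normalized confusion matrices and impurity-decrease feature importances.

Three search drivers sit on top:

- :func:`window_length_sweep` — stage 1, one round per window length, with a
  plateau rule choosing the shortest length whose accuracy is within a
  tolerance of the sweep maximum;
- :func:`configuration_sweep` — stage 2, one round per sensor configuration
  at a fixed window length, features re-extracted per configuration;
- :func:`rank_and_eliminate` — stage 3, recursive elimination of the least
  informative feature, one evaluation round per feature count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from solewalk.features import DEFAULT_PARAMS, FeatureParams, extract_matrix
from solewalk.sensor_config import SensorConfiguration
from solewalk.signal_io import ACTIVITIES, PressureRecording

#: Non-feature columns of a feature matrix.
META_COLUMNS: tuple[str, ...] = ("subject_id", "activity", "window_start_s")

_SEED_CAP = 2**31 - 1


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# assignments


@dataclass(frozen=True)
class AssignmentPlan:
    """One subject-wise train/test split plus its per-run forest seeds."""

    assignment_id: int
    train_subjects: frozenset[str]
    test_subjects: frozenset[str]
    random_states: tuple[int, ...]

    def __post_init__(self):
        if self.train_subjects & self.test_subjects:
            raise ValueError("train and test subjects overlap")


def roster_from_recordings(recordings: list[PressureRecording]) -> dict[str, set[str]]:
    """subject_id -> set of activities present in the cohort."""
    roster: dict[str, set[str]] = {}
    for rec in recordings:
        roster.setdefault(rec.subject_id, set()).add(rec.activity)
    return roster


def make_assignments(
    roster: dict[str, set[str]],
    n_assignments: int = 5,
    n_train: int = 6,
    seed: int = 0,
    n_random_states: int = 20,
) -> list[AssignmentPlan]:
    """Draw subject-wise hold-out plans.

    Training subjects are sampled only from subjects who completed all nine
    activities; everyone else (including incomplete subjects) goes to the
    test side. The ``n_assignments`` train sets are distinct, and each plan
    carries ``n_random_states`` forest seeds drawn from the same master seed,
    so a fixed seed reproduces the full 100-forest round bit-identically.
    """
    complete = sorted(s for s, acts in roster.items() if set(ACTIVITIES) <= acts)
    if len(complete) < n_train:
        raise ValueError(
            f"need at least {n_train} subjects with all {len(ACTIVITIES)} activities, "
            f"found {len(complete)}"
        )
    all_subjects = sorted(roster)
    rng = np.random.default_rng(seed)
    plans: list[AssignmentPlan] = []
    seen: set[frozenset[str]] = set()
    guard = 0
    while len(plans) < n_assignments:
        train = frozenset(rng.choice(complete, size=n_train, replace=False))
        guard += 1
        if guard > 10_000:
            raise ValueError("cannot draw enough distinct train sets from the roster")
        if train in seen:
            continue
        seen.add(train)
        states = tuple(int(v) for v in rng.integers(0, _SEED_CAP, size=n_random_states))
        plans.append(AssignmentPlan(
            assignment_id=len(plans) + 1,
            train_subjects=train,
            test_subjects=frozenset(s for s in all_subjects if s not in train),
            random_states=states,
        ))
    return plans


# ---------------------------------------------------------------------------
# forests


@dataclass(frozen=True)
class ForestSpec:
    """Random-forest hyperparameters: 100 bagged gini trees grown to purity.

    ``max_features`` is the number of candidate features per split
    (square-root heuristic by default).
    """

    n_trees: int = 100
    split_criterion: str = "gini"
    bootstrap: bool = True
    max_features: str | int | float = "sqrt"

    def build(self, random_state: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion=self.split_criterion,
            bootstrap=self.bootstrap,
            max_features=self.max_features,
            max_depth=None,            # grow until leaves are pure
            min_samples_split=2,
            random_state=random_state,
            n_jobs=1,
        )


def train_forest(X, y, spec: ForestSpec = ForestSpec(), random_state: int = 0):
    """Fit one forest; prediction is the mode over the pure trees' votes
    (class-label order breaks exact ties)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain at least 2 classes")
    forest = spec.build(random_state)
    forest.fit(X, y)
    return forest


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class AssignmentResult:
    """Aggregates of the forests of one assignment (fixed test set)."""

    assignment_id: int
    accuracies: np.ndarray            # one per random state
    confusion: np.ndarray             # row-normalized, averaged over forests
    support: np.ndarray               # test windows per activity


@dataclass
class EvaluationResult:
    """Aggregates of one evaluation round (all assignments x random states)."""

    per_forest_accuracy: np.ndarray
    confusion: np.ndarray                       # 9x9, rows ~ true activity
    per_activity_sensitivity: np.ndarray        # diagonal of ``confusion``
    feature_importances: pd.Series              # mean over forests, by feature id
    per_assignment: list[AssignmentResult] = field(default_factory=list)
    activities: tuple[str, ...] = ACTIVITIES

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_forest_accuracy.mean())

    @property
    def min_accuracy(self) -> float:
        return float(self.per_forest_accuracy.min())

    @property
    def max_accuracy(self) -> float:
        return float(self.per_forest_accuracy.max())

    def sensitivity(self, activity: str) -> float:
        return float(self.per_activity_sensitivity[self.activities.index(activity)])


def _nanmean_stack(arrays: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean ignoring NaNs; NaN where every element is NaN."""
    stack = np.stack(arrays)
    mask = np.isfinite(stack)
    total = np.where(mask, stack, 0.0).sum(axis=0)
    count = mask.sum(axis=0)
    out = np.full(stack.shape[1:], np.nan)
    seen = count > 0
    out[seen] = total[seen] / count[seen]
    return out


def _row_normalized_confusion(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    k = len(ACTIVITIES)
    index = {a: i for i, a in enumerate(ACTIVITIES)}
    counts = np.zeros((k, k))
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    support = counts.sum(axis=1)
    norm = np.full((k, k), np.nan)
    rows = support > 0
    norm[rows] = counts[rows] / support[rows, None]
    return norm, support


def evaluate_round(
    feature_matrix: pd.DataFrame,
    plans: list[AssignmentPlan],
    spec: ForestSpec = ForestSpec(),
) -> EvaluationResult:
    """Train and test every (assignment, random state) forest and aggregate.

    Enforces subject-wise integrity: a window of a training subject can never
    be scored, and per forest the support-weighted confusion trace must equal
    the accuracy to numerical precision.
    """
    cols = feature_columns(feature_matrix)
    subjects = feature_matrix["subject_id"].to_numpy()
    y_all = feature_matrix["activity"].to_numpy()
    X_all = feature_matrix[cols].to_numpy(dtype=float)

    all_acc: list[float] = []
    importances = np.zeros(len(cols))
    confusions: list[np.ndarray] = []
    per_assignment: list[AssignmentResult] = []
    n_forests = 0
    for plan in plans:
        train_mask = np.isin(subjects, sorted(plan.train_subjects))
        test_mask = np.isin(subjects, sorted(plan.test_subjects))
        if np.any(train_mask & test_mask):  # pragma: no cover - guarded by plan invariant
            raise AssertionError("subject leakage between train and test windows")
        X_tr, y_tr = X_all[train_mask], y_all[train_mask]
        X_te, y_te = X_all[test_mask], y_all[test_mask]
        if len(y_te) == 0:
            raise ValueError(f"assignment {plan.assignment_id}: empty test set")
        plan_acc = []
        plan_conf: list[np.ndarray] = []
        support = None
        for rs in plan.random_states:
            forest = train_forest(X_tr, y_tr, spec, random_state=rs)
            y_pred = forest.predict(X_te)
            acc = float(np.mean(y_pred == y_te))
            conf, support = _row_normalized_confusion(y_te, y_pred)
            trace = np.nansum(np.where(support > 0, np.diag(conf) * support, 0.0))
            if abs(trace / support.sum() - acc) > 1e-9:
                raise AssertionError("confusion trace inconsistent with accuracy")
            plan_acc.append(acc)
            plan_conf.append(conf)
            importances += forest.feature_importances_
            n_forests += 1
        all_acc.extend(plan_acc)
        confusions.extend(plan_conf)
        avg_conf = _nanmean_stack(plan_conf)
        per_assignment.append(AssignmentResult(
            assignment_id=plan.assignment_id,
            accuracies=np.asarray(plan_acc),
            confusion=avg_conf,
            support=support,
        ))
    confusion = _nanmean_stack(confusions)
    return EvaluationResult(
        per_forest_accuracy=np.asarray(all_acc),
        confusion=confusion,
        per_activity_sensitivity=np.diag(confusion).copy(),
        feature_importances=pd.Series(importances / n_forests, index=cols),
        per_assignment=per_assignment,
    )


# ---------------------------------------------------------------------------
# stage 3: recursive feature elimination


@dataclass
class EliminationRound:
    n_features: int
    result: EvaluationResult
    removed_feature: str | None     # None in the final round


def rank_and_eliminate(
    feature_matrix: pd.DataFrame,
    plans: list[AssignmentPlan],
    spec: ForestSpec = ForestSpec(),
    min_features: int = 1,
    verbose: bool = False,
) -> list[EliminationRound]:
    """Backward elimination by mean impurity-decrease importance.

    Each round evaluates the current feature set, then drops the single
    feature with the smallest mean importance across the round's forests
    (ties broken by catalog column order). Runs until ``min_features``
    remain (1 by default), evaluating that final set too.
    """
    cols = feature_columns(feature_matrix)
    if not 1 <= min_features <= len(cols):
        raise ValueError("min_features must be in 1..n_features")
    meta = feature_matrix[list(META_COLUMNS)]
    current = list(cols)
    trace: list[EliminationRound] = []
    while True:
        sub = pd.concat([feature_matrix[current], meta], axis=1)
        result = evaluate_round(sub, plans, spec)
        if len(current) == min_features:
            trace.append(EliminationRound(len(current), result, None))
            break
        imp = result.feature_importances.to_numpy()
        removed = current[int(np.argmin(imp))]   # first minimum = catalog order
        trace.append(EliminationRound(len(current), result, removed))
        if verbose:  # pragma: no cover
            print(f"  {len(current):4d} features: mean acc "
                  f"{result.mean_accuracy:.3f}; removing {removed}")
        current.remove(removed)
    return trace


# ---------------------------------------------------------------------------
# stages 1-2: window-length and sensor-configuration sweeps


@dataclass
class WindowSweepResult:
    results: dict[float, EvaluationResult]
    optimum_length_s: float


def select_optimum_length(
    results: dict[float, EvaluationResult], delta: float = 0.01
) -> float:
    """Smallest window length whose mean accuracy is within ``delta`` of the
    sweep maximum — the point where accuracy vs length has flattened, which
    preserves the highest temporal resolution among near-optimal lengths."""
    means = {L: r.mean_accuracy for L, r in results.items()}
    best = max(means.values())
    return min(L for L, m in means.items() if m >= best - delta)


def window_length_sweep(
    recordings: list[PressureRecording],
    lengths: tuple[float, ...],
    config: SensorConfiguration,
    plans: list[AssignmentPlan],
    spec: ForestSpec = ForestSpec(),
    params: FeatureParams = DEFAULT_PARAMS,
    delta: float = 0.01,
) -> WindowSweepResult:
    """Stage 1: one full evaluation round per window length, features
    re-extracted at each length."""
    if not lengths:
        raise ValueError("at least one window length is required")
    results = {}
    for L in lengths:
        matrix = extract_matrix(recordings, L, config, params)
        results[L] = evaluate_round(matrix, plans, spec)
    return WindowSweepResult(results, select_optimum_length(results, delta))


def configuration_sweep(
    recordings: list[PressureRecording],
    configs: list[SensorConfiguration],
    window_s: float,
    plans: list[AssignmentPlan],
    spec: ForestSpec = ForestSpec(),
    params: FeatureParams = DEFAULT_PARAMS,
) -> dict[str, EvaluationResult]:
    """Stage 2: independent evaluation per sensor configuration at a fixed
    window length; each configuration carries its own feature count."""
    if not configs:
        raise ValueError("at least one configuration is required")
    out = {}
    for config in configs:
        matrix = extract_matrix(recordings, window_s, config, params)
        out[config.label] = evaluate_round(matrix, plans, spec)
    return out
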