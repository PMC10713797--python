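"""End-to-end orchestration: align → extract → select → adapt → evaluate.

Tasks follow two cross-subject strategies: STS (single source to single
target — every ordered subject pair) and MTS (multi source to single target
— each subject once as target, all others pooled as source).  Multi-class
label sets are decomposed into all unordered class pairs, each solved as an
independent binary task; no fusion into a multi-class prediction is
performed.

Ground-truth target labels exist only for evaluation: the fitting path
receives an unlabeled target FeatureSet and never sees them.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .adapt import (
    AdaptConfig,
    AdaptResult,
    class_prototypes,
    fit_dsktl_binary,
    pseudo_label_probabilities,
)
from .exceptions import InvalidInputError
from .mefs import fit_mefs, select_features
from .spd import (
    FeatureSet,
    MeanKind,
    TrialSet,
    align_trials,
    mean_covariance,
    tangent_space_map,
    trial_covariances,
)

__all__ = [
    "MEFSConfig",
    "TaskSpec",
    "TaskResult",
    "EvalReport",
    "enumerate_tasks",
    "extract_features",
    "run_task",
    "run_tasks",
    "no_adaptation_baseline",
    "evaluate",
]


@dataclass
class MEFSConfig:
    """Feature-selection settings for a task (defaults α=1, β=1, γ=100)."""

    q: int = 10
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 100.0
    max_iter: int = 20
    tol: float = 1e-6
    bandwidth: float | str = "auto"
    k_neighbors: int | None = None
    n_restarts: int = 1
    seed: int | None = 0
    disable_feature_selection: bool = False


@dataclass
class TaskSpec:
    """One binary cross-subject classification task."""

    strategy: str
    target_subject: str
    source_subjects: list
    class_pair: tuple
    mean_kind: MeanKind = "euclidean"
    mefs: MEFSConfig = field(default_factory=MEFSConfig)
    adapt: AdaptConfig = field(default_factory=AdaptConfig)
    per_domain_reference: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in ("MTS", "STS"):
            raise InvalidInputError("strategy must be 'MTS' or 'STS'")
        if self.target_subject in self.source_subjects:
            raise InvalidInputError("target subject may not appear among sources")
        if len(self.class_pair) != 2 or self.class_pair[0] == self.class_pair[1]:
            raise InvalidInputError("class_pair must hold two distinct classes")


@dataclass
class TaskResult:
    """Per-task outcome: predictions plus bookkeeping."""

    task: TaskSpec
    adapt_result: AdaptResult
    accuracy: float | None
    baseline_accuracy: float | None
    n_target: int
    stage_seconds: dict


@dataclass
class EvalReport:
    """Aggregate accuracies over a collection of tasks."""

    per_task: list
    per_target_mean: dict
    grand_mean: float
    grand_std: float


def enumerate_tasks(
    subject_ids: list,
    strategy: str,
    class_labels: list,
    mean_kind: MeanKind = "euclidean",
    mefs: MEFSConfig | None = None,
    adapt: AdaptConfig | None = None,
) -> list[TaskSpec]:
    """All TaskSpecs for a subject pool, strategy, and label set.

    STS yields every ordered (source, target) pair — m(m−1) arrangements;
    MTS yields one arrangement per target with all other subjects as
    sources.  Label sets with more than two classes expand into all
    C(C−1)/2 unordered pairs per arrangement.
    """
    if len(subject_ids) < 2:
        raise InvalidInputError("need at least two subjects")
    classes = sorted(set(class_labels))
    if len(classes) < 2:
        raise InvalidInputError("need at least two classes")
    pairs = list(itertools.combinations(classes, 2))
    mefs = mefs or MEFSConfig()
    adapt = adapt or AdaptConfig()

    arrangements: list[tuple[str, list]] = []
    if strategy == "STS":
        for src, tgt in itertools.permutations(subject_ids, 2):
            arrangements.append((tgt, [src]))
    elif strategy == "MTS":
        for tgt in subject_ids:
            arrangements.append((tgt, [s for s in subject_ids if s != tgt]))
    else:
        raise InvalidInputError("strategy must be 'MTS' or 'STS'")

    return [
        TaskSpec(
            strategy=strategy,
            target_subject=tgt,
            source_subjects=srcs,
            class_pair=pair,
            mean_kind=mean_kind,
            mefs=mefs,
            adapt=adapt,
        )
        for tgt, srcs in arrangements
        for pair in pairs
    ]


def _subset_classes(ts: TrialSet, class_pair: tuple) -> TrialSet:
    if ts.labels is None:
        return ts
    mask = np.isin(ts.labels, list(class_pair))
    if not mask.any():
        raise InvalidInputError(
            f"subject {ts.subject_id!r} has no trials for classes {class_pair}"
        )
    return TrialSet(
        trials=ts.trials[mask],
        labels=ts.labels[mask],
        subject_id=ts.subject_id,
        sampling_rate=ts.sampling_rate,
    )


def extract_features(
    task: TaskSpec, data: dict
) -> tuple[FeatureSet, FeatureSet, np.ndarray]:
    """Align, estimate covariances and tangent-map all task subjects.

    Each subject is aligned individually with the task's centroid mean;
    aligned source subjects are then concatenated.  The tangent reference is
    the pooled mean over all aligned covariances (sources and target
    together) — after alignment every subject's centroid is near the
    identity, so a shared reference is well defined; a per-domain reference
    is available via ``task.per_domain_reference``.

    Returns the pooled labeled source FeatureSet, the unlabeled target
    FeatureSet, and the held-back target ground-truth labels (or None).
    """
    missing = [
        s for s in [*task.source_subjects, task.target_subject] if s not in data
    ]
    if missing:
        raise InvalidInputError(f"missing subjects: {missing}")
    for sid in task.source_subjects:
        if data[sid].labels is None or not all(
            np.any(data[sid].labels == c) for c in task.class_pair
        ):
            raise InvalidInputError(
                f"source subject {sid!r} lacks a class of {task.class_pair}"
            )

    src_covs, src_labels = [], []
    for sid in task.source_subjects:
        sub = _subset_classes(data[sid], task.class_pair)
        aligned = align_trials(sub, mean_kind=task.mean_kind)
        src_covs.append(trial_covariances(aligned))
        src_labels.append(sub.labels)
    tgt = _subset_classes(data[task.target_subject], task.class_pair)
    tgt_aligned = align_trials(tgt, mean_kind=task.mean_kind)
    tgt_covs = trial_covariances(tgt_aligned)

    all_src_covs = np.concatenate(src_covs)
    y_s = np.concatenate(src_labels)
    if task.per_domain_reference:
        ref_s = mean_covariance(all_src_covs, kind=task.mean_kind)
        ref_t = mean_covariance(tgt_covs, kind=task.mean_kind)
    else:
        ref_s = ref_t = mean_covariance(
            np.concatenate([all_src_covs, tgt_covs]), kind=task.mean_kind
        )
    f_s = tangent_space_map(all_src_covs, ref_s, labels=y_s, domain_tag="source")
    f_t = tangent_space_map(tgt_covs, ref_t, domain_tag="target")
    return f_s, f_t, (tgt.labels.copy() if tgt.labels is not None else None)


def no_adaptation_baseline(
    f_s: FeatureSet, y_s: np.ndarray, f_t: FeatureSet
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-class-prototype classification with no learned transform.

    Prototypes are class means directly in the (selected) feature space and
    target samples get soft labels from the same softmax-over-distances rule
    used inside the adaptation loop — the reference point the adaptation has
    to beat.
    """
    classes = np.unique(y_s)
    protos = class_prototypes(f_s.features, y_s, classes)
    probs, labels = pseudo_label_probabilities(f_t.features, protos, classes)
    return labels, probs


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of correct target predictions (exact count, then float)."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise InvalidInputError("predictions and truth differ in length")
    if predictions.size == 0:
        raise InvalidInputError("empty target set")
    return float(Fraction(int(np.sum(predictions == truth)), int(truth.size)))


def run_task(task: TaskSpec, data: dict) -> TaskResult:
    """Execute one task end to end and score it when truth is available."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    f_s, f_t, y_truth = extract_features(task, data)
    timings["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if task.mefs.disable_feature_selection:
        f_s_sel, f_t_sel = f_s, f_t
    else:
        model = fit_mefs(
            f_s,
            alpha=task.mefs.alpha,
            beta=task.mefs.beta,
            gamma=task.mefs.gamma,
            max_iter=task.mefs.max_iter,
            tol=task.mefs.tol,
            bandwidth=task.mefs.bandwidth,
            k_neighbors=task.mefs.k_neighbors,
            n_restarts=task.mefs.n_restarts,
            seed=task.mefs.seed,
        )
        q = min(task.mefs.q, f_s.dim)
        f_s_sel = select_features(model, f_s, q)
        f_t_sel = select_features(model, f_t, q)
    timings["selection"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result = fit_dsktl_binary(f_s_sel, f_t_sel, task.adapt)
    timings["adaptation"] = time.perf_counter() - t0

    accuracy = baseline = None
    if y_truth is not None:
        accuracy = evaluate(result.pseudo_labels, y_truth)
        base_labels, _ = no_adaptation_baseline(f_s_sel, f_s_sel.labels, f_t_sel)
        baseline = evaluate(base_labels, y_truth)
    return TaskResult(
        task=task,
        adapt_result=result,
        accuracy=accuracy,
        baseline_accuracy=baseline,
        n_target=f_t.n,
        stage_seconds=timings,
    )


def run_tasks(tasks: list[TaskSpec], data: dict) -> EvalReport:
    """Run a task list and aggregate accuracies per target subject."""
    results = [run_task(t, data) for t in tasks]
    by_target: dict[str, list[float]] = {}
    for r in results:
        if r.accuracy is not None:
            by_target.setdefault(r.task.target_subject, []).append(r.accuracy)
    per_target = {k: float(np.mean(v)) for k, v in sorted(by_target.items())}
    means = list(per_target.values())
    return EvalReport(
        per_task=results,
        per_target_mean=per_target,
        grand_mean=float(np.mean(means)) if means else float("nan"),
        grand_std=float(np.std(means)) if means else float("nan"),
    )
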