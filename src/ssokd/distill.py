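"""Knowledge distillation: losses, the teacher-student grid protocol and
the comparability hypothesis test.

The student is trained against a convex combination of two cross-entropies,
``L = alpha * L_soft + (1 - alpha) * L_hard``: the soft term compares the
student's temperature-softened class distribution with the (frozen)
teacher's at the same temperature T, the hard term is ordinary
cross-entropy against the ground-truth one-hot label. No 1/T^2 rescaling is
applied to the soft term. Teacher-student comparability is judged by a
two-tailed paired t-test on per-seed accuracies at significance alpha=0.05,
i.e. the student is "comparable" when p >= 0.025.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fusion import FusionClassifier, ModelConfig, TrainConfig
from . import nn

__all__ = [
    "KDConfig", "DistillationResult",
    "temperature_softmax", "soft_loss", "hard_loss", "combined_loss",
    "distill", "distillation_grid", "comparability_test",
]


@dataclass(frozen=True)
class KDConfig:
    """alpha weights the soft (teacher) loss; T softens both distributions.

    The default puts most of the weight on the teacher's soft targets
    (alpha = 0.9), the regime in which distillation from a clearly stronger
    teacher transfers most of its advantage; alpha = 0 recovers plain
    hard-label training.
    """

    alpha: float = 0.9
    temperature: float = 5.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


@dataclass
class DistillationResult:
    teacher_name: str
    student_name: str
    teacher_accuracy: float
    student_accuracy_before: float
    student_accuracy_after: float

    @property
    def delta(self) -> float:
        return self.student_accuracy_after - self.student_accuracy_before


# ---- loss primitives ------------------------------------------------------

def temperature_softmax(logits, T: float) -> np.ndarray:
    """Softmax of logits/T with max-subtraction for overflow safety; T=1 is
    the standard softmax."""
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    z = np.asarray(logits, dtype=float) / T
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    return nn.softmax(z)


def soft_loss(teacher_logits, student_logits, T: float) -> float:
    """Cross-entropy between teacher and student temperature-softened
    distributions: -sum_i p_i^T log q_i^T."""
    t = np.asarray(teacher_logits, dtype=float)
    s = np.asarray(student_logits, dtype=float)
    if t.shape != s.shape:
        raise ValueError(f"logit shapes differ: {t.shape} vs {s.shape}")
    p = temperature_softmax(t, T)
    q = temperature_softmax(s, T)
    return float(-np.sum(p * np.log(np.clip(q, 1e-300, None))))


def hard_loss(student_logits, onehot) -> float:
    """Cross-entropy against the one-hot ground truth at T=1."""
    c = np.asarray(onehot, dtype=float)
    if not (np.all((c == 0) | (c == 1)) and np.isclose(c.sum(), 1.0)):
        raise ValueError("label must be one-hot")
    q = temperature_softmax(student_logits, 1.0)
    return float(-np.sum(c * np.log(np.clip(q, 1e-300, None))))


def combined_loss(teacher_logits, student_logits, onehot, kd: KDConfig) -> float:
    """alpha * soft + (1 - alpha) * hard."""
    return (kd.alpha * soft_loss(teacher_logits, student_logits, kd.temperature)
            + (1.0 - kd.alpha) * hard_loss(student_logits, onehot))


def _kd_batch_loss_grad(student_logits: np.ndarray, teacher_logits: np.ndarray,
                        onehot: np.ndarray, kd: KDConfig):
    """Batch-mean combined loss and its gradient w.r.t. the student logits."""
    n = student_logits.shape[0]
    T = kd.temperature
    p = nn.softmax(teacher_logits / T)
    q = nn.softmax(student_logits / T)
    q1 = nn.softmax(student_logits)
    soft = -np.sum(p * np.log(np.clip(q, 1e-300, None))) / n
    hard = -np.sum(onehot * np.log(np.clip(q1, 1e-300, None))) / n
    loss = kd.alpha * soft + (1.0 - kd.alpha) * hard
    grad = (kd.alpha * (q - p) / T + (1.0 - kd.alpha) * (q1 - onehot)) / n
    return float(loss), grad


# ---- distillation protocol ------------------------------------------------

def _accuracy(model: FusionClassifier, triple) -> float:
    x, t, y = triple
    return float(np.mean(model.predict(x, t) == np.asarray(y)))


def distill(teacher: FusionClassifier, student_config: ModelConfig,
            data, tc: TrainConfig = TrainConfig(),
            kd: KDConfig = KDConfig(), student_name: str = "student",
            teacher_name: str = "teacher",
            train_baseline: bool = True) -> tuple[DistillationResult, FusionClassifier]:
    """Train a student twice from the same initialization seed -- once with
    hard labels only ("before"), once with the combined distillation loss
    against the trained teacher's frozen logits ("after") -- and report test
    accuracies of both alongside the teacher's.

    ``data`` is an object with ``train``/``validation``/``test`` attributes,
    each an ``(images, tabular, labels)`` triple. Returns the result record
    and the distilled student. ``train_baseline=False`` skips the "before"
    run (reported as NaN) when only the distilled model is needed.
    """
    x_tr, t_tr, y_tr = data.train
    teacher_logits = teacher.logits(x_tr, t_tr)
    if teacher_logits.shape[0] != len(x_tr):
        raise ValueError("teacher/student input size mismatch")
    onehot_tr = np.eye(2)[np.asarray(y_tr, dtype=int)]

    before_acc = float("nan")
    if train_baseline:
        baseline = FusionClassifier(student_config, input_shape=teacher.input_shape,
                                    n_tabular=teacher.n_tabular, seed=tc.seed)
        baseline.fit(data.train, data.validation, tc)
        before_acc = _accuracy(baseline, data.test)

    student = FusionClassifier(student_config, input_shape=teacher.input_shape,
                               n_tabular=teacher.n_tabular, seed=tc.seed)

    def kd_loss(logits, idx):
        return _kd_batch_loss_grad(logits, teacher_logits[idx], onehot_tr[idx], kd)

    student.fit(data.train, data.validation, tc, loss_grad=kd_loss)

    result = DistillationResult(
        teacher_name=teacher_name,
        student_name=student_name,
        teacher_accuracy=_accuracy(teacher, data.test),
        student_accuracy_before=before_acc,
        student_accuracy_after=_accuracy(student, data.test),
    )
    return result, student


def distillation_grid(teachers: dict[str, FusionClassifier],
                      students: dict[str, ModelConfig],
                      data, tc: TrainConfig = TrainConfig(),
                      kd: KDConfig = KDConfig()):
    """Run every teacher x student pair (the 3x3 protocol yields nine).

    Returns ``(results, report)`` where report is a DataFrame with one row
    per pair (teacher, student, accuracies, delta in percentage points) --
    the grid-table layout -- plus the mean delta across cells.
    """
    if not teachers or not students:
        raise ValueError("need at least one teacher and one student")
    results: list[DistillationResult] = []
    models: dict[tuple[str, str], FusionClassifier] = {}
    for t_name, teacher in teachers.items():
        for s_name, s_config in students.items():
            res, model = distill(teacher, s_config, data, tc, kd,
                                 student_name=s_name, teacher_name=t_name)
            results.append(res)
            models[(t_name, s_name)] = model
    report = grid_report(results)
    return results, report, models


def grid_report(results: list[DistillationResult]) -> pd.DataFrame:
    """Tabulate distillation results (accuracies and delta in percent)."""
    rows = [{
        "teacher": r.teacher_name,
        "student": r.student_name,
        "teacher_acc_pct": round(100 * r.teacher_accuracy, 2),
        "before_pct": round(100 * r.student_accuracy_before, 2),
        "after_pct": round(100 * r.student_accuracy_after, 2),
        "delta_pct": round(100 * r.delta, 2),
    } for r in results]
    df = pd.DataFrame(rows)
    df.attrs["mean_delta_pct"] = float(np.mean([100 * r.delta for r in results]))
    return df


# ---- comparability test ---------------------------------------------------

def comparability_test(teacher_accuracies, student_accuracies,
                       significance: float = 0.05) -> dict:
    """Two-tailed paired t-test of H0: mean student accuracy equals mean
    teacher accuracy. Verdict is "comparable" iff p >= significance/2."""
    t_acc = np.asarray(teacher_accuracies, dtype=float)
    s_acc = np.asarray(student_accuracies, dtype=float)
    if t_acc.shape != s_acc.shape or t_acc.ndim != 1:
        raise ValueError("need equal-length 1-D paired accuracy lists")
    if len(t_acc) < 2:
        raise ValueError("need at least two paired replicates")
    diffs = s_acc - t_acc
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences: t-test degenerate")
    t_stat, p = stats.ttest_rel(s_acc, t_acc)
    threshold = significance / 2.0
    return {
        "t_statistic": float(t_stat),
        "p_value": float(p),
        "threshold": threshold,
        "verdict": "comparable" if p >= threshold else "not comparable",
    }
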