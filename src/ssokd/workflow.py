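"""The two-stage lightweight-model construction workflow.

Stage 1 trains large teacher fusion models, distills each into every small
student (the teacher x student grid), tests teacher-student comparability
by a paired t-test over seed replicates, and selects the comparable
student with the highest post-distillation accuracy (ties break toward
fewer parameters; if no student is comparable the highest-accuracy one is
selected with a warning). Stage 2 freezes the selected student's
convolutional feature extractor and runs Simplified Swarm Optimization
over the seven head hyperparameters, with validation accuracy of the
decoded model as the fitness; the test split is touched exactly once, for
the final report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import evaluation, preprocessing, sso
from .distill import KDConfig, distill, grid_report, comparability_test
from .fusion import (SOLUTION_BOUNDS, FusionClassifier, ModelConfig,
                     TrainConfig, decode_solution)
from .pipeline import SplitDataset, augment_fourfold, stratified_split
from .preprocessing import PreprocessConfig, Standardizer
from .synthetic import SyntheticSpec, generate_dataset

__all__ = ["WorkflowConfig", "ArraySplit", "Stage1Result", "Stage2Result",
           "prepare_arrays", "run_stage1", "run_stage2", "run_all"]

# ordinal column ranges used to scale [breast_density, birads, subtlety]
_ORDINAL_SCALE = np.array([4.0, 5.0, 5.0])


@dataclass
class ArraySplit:
    """Model-ready arrays: each split is an (images, tabular, labels) triple
    with NHWC images."""

    train: tuple
    validation: tuple
    test: tuple
    standardizer: Standardizer = field(default_factory=Standardizer)


@dataclass(frozen=True)
class WorkflowConfig:
    synthetic: SyntheticSpec = SyntheticSpec()
    preprocess: PreprocessConfig = PreprocessConfig(target_shape=(32, 32, 1))
    train: TrainConfig = TrainConfig(epochs=12)
    kd: KDConfig = KDConfig()
    sso_params: sso.SSOParams = sso.SSOParams(n_gen=4, n_sol=4)
    # teacher/student rosters: name -> (backbone, head solution)
    teachers: dict = field(default_factory=lambda: {
        "wide": ("tiny-wide", (64, 20, 64, 20, 64, 20, 50)),
    })
    students: dict = field(default_factory=lambda: {
        "tiny": ("tiny", (10, 20, 40, 20, 100, 20, 50)),
    })
    n_replicates: int = 5
    augment: bool = True
    use_nlm: bool = False
    use_clahe: bool = False
    remove_borders: bool = True
    sso_epochs: int = 8
    seed: int = 0


def _preprocess_image(img, cfg: WorkflowConfig):
    x = img
    if cfg.remove_borders:
        try:
            x = preprocessing.remove_white_border(x, cfg.preprocess)
        except ValueError:
            pass  # fully saturated degenerate image: keep as is
    if cfg.use_nlm:
        x = preprocessing.nlm_denoise(x, cfg.preprocess)
    if cfg.use_clahe:
        x = preprocessing.clahe_enhance(x, cfg.preprocess)
    return x


def prepare_arrays(split: SplitDataset, cfg: WorkflowConfig) -> ArraySplit:
    """Preprocess and encode a split into model-ready arrays.

    Augmentation (when enabled) is applied to the training split only --
    validation and test stay untouched (leakage guard) -- and the pixel
    standardizer is fitted on the training images alone.
    """
    train_samples = split.train
    if cfg.augment:
        train_samples = augment_fourfold(train_samples, seed=cfg.seed)
    assert len(split.validation) + len(split.test) == \
        split.n_samples - len(split.train), "augmentation leaked out of train"

    h, w, c = cfg.preprocess.target_shape

    def images_of(samples, mean, sd):
        arr = np.stack([
            preprocessing.resize_and_standardize(
                _preprocess_image(s.image, cfg), cfg.preprocess, mean, sd)
            for s in samples])
        return arr

    # two-pass contract: moments from the (preprocessed, resized) train set
    raw_train = np.stack([
        preprocessing.resize_and_standardize(
            _preprocess_image(s.image, cfg), cfg.preprocess, 0.0, 1.0)
        for s in train_samples])
    std = Standardizer(mean=float(raw_train.mean()),
                       sd=float(raw_train.std()) or 1.0)

    def triple(samples, images=None):
        images = images_of(samples, std.mean, std.sd) if images is None else images
        tab = preprocessing.encode_tabular([s.record for s in samples])
        tab = tab.astype(float)
        tab[:, :3] = tab[:, :3] / _ORDINAL_SCALE
        y = np.array([s.label for s in samples], dtype=int)
        return (images, tab, y)

    return ArraySplit(
        train=triple(train_samples, images=(raw_train - std.mean) / std.sd),
        validation=triple(split.validation),
        test=triple(split.test),
        standardizer=std,
    )


def _build_model(name_spec, input_shape, seed, n_tabular=44) -> FusionClassifier:
    backbone_name, solution = name_spec
    config = decode_solution(tuple(solution), backbone_name=backbone_name)
    return FusionClassifier(config, input_shape=input_shape, seed=seed,
                            n_tabular=n_tabular)


@dataclass
class Stage1Result:
    grid_results: list
    report: object
    comparability: dict
    accuracies: dict
    selected_pair: tuple[str, str]
    selected_student: FusionClassifier
    selected_teacher: FusionClassifier
    student_test_accuracy: float
    fallback_used: bool
    data: ArraySplit


def run_stage1(cfg: WorkflowConfig, data: ArraySplit | None = None) -> Stage1Result:
    """Teacher training, the distillation grid over seed replicates,
    comparability testing and student selection."""
    if data is None:
        samples = generate_dataset(cfg.synthetic)
        split = stratified_split(samples, seed=cfg.seed)
        data = prepare_arrays(split, cfg)
    input_shape = data.train[0].shape[1:]

    teacher_acc: dict[tuple[str, str], list[float]] = {}
    student_acc: dict[tuple[str, str], list[float]] = {}
    all_results = []
    for r in range(cfg.n_replicates):
        seed_r = int(np.random.SeedSequence([cfg.seed, 101, r]).generate_state(1)[0]
                     % (2 ** 31))
        tc_r = dataclasses.replace(cfg.train, seed=seed_r)
        for t_name, t_spec in cfg.teachers.items():
            teacher = _build_model(t_spec, input_shape, seed_r)
            teacher.fit(data.train, data.validation, tc_r)
            for s_name, s_spec in cfg.students.items():
                s_config = decode_solution(tuple(s_spec[1]), backbone_name=s_spec[0])
                res, _model = distill(teacher, s_config, data, tc_r, cfg.kd,
                                      student_name=s_name, teacher_name=t_name)
                all_results.append(res)
                key = (t_name, s_name)
                teacher_acc.setdefault(key, []).append(res.teacher_accuracy)
                student_acc.setdefault(key, []).append(res.student_accuracy_after)

    comparability = {}
    for key in teacher_acc:
        try:
            comparability[key] = comparability_test(teacher_acc[key], student_acc[key])
        except ValueError as exc:  # degenerate (e.g. zero-variance differences)
            comparability[key] = {"verdict": "degenerate", "error": str(exc)}

    mean_after = {k: float(np.mean(v)) for k, v in student_acc.items()}
    comparable = [k for k, c in comparability.items()
                  if c.get("verdict") == "comparable"]
    fallback = len(comparable) == 0
    pool = list(mean_after) if fallback else comparable
    if fallback:
        warnings.warn("no student was comparable to its teacher; "
                      "selecting the highest-accuracy student instead")

    def param_count(key):
        s_spec = cfg.students[key[1]]
        m = _build_model(s_spec, input_shape, 0)
        return m.parameter_count

    best = max(pool, key=lambda k: (mean_after[k], -param_count(k)))

    # re-run the selected pair at the base seed to produce the carried models
    tc0 = dataclasses.replace(cfg.train, seed=cfg.seed)
    teacher = _build_model(cfg.teachers[best[0]], input_shape, cfg.seed)
    teacher.fit(data.train, data.validation, tc0)
    s_spec = cfg.students[best[1]]
    s_config = decode_solution(tuple(s_spec[1]), backbone_name=s_spec[0])
    res, student = distill(teacher, s_config, data, tc0, cfg.kd,
                           student_name=best[1], teacher_name=best[0])
    return Stage1Result(
        grid_results=all_results,
        report=grid_report(all_results),
        comparability=comparability,
        accuracies={"teacher": teacher_acc, "student_after": student_acc},
        selected_pair=best,
        selected_student=student,
        selected_teacher=teacher,
        student_test_accuracy=res.student_accuracy_after,
        fallback_used=fallback,
        data=data,
    )


@dataclass
class Stage2Result:
    best_solution: tuple
    best_fitness: float
    history: list[float]
    final_config: ModelConfig
    test_metrics: evaluation.MetricsReport
    test_accuracy: float
    compression_pct: float
    n_fitness_evaluations: int


def run_stage2(cfg: WorkflowConfig, stage1: Stage1Result) -> Stage2Result:
    """SSO over the seven head hyperparameters with the stage-1 student's
    feature extractor frozen; fitness is validation accuracy."""
    data = stage1.data
    student = stage1.selected_student
    feats = {
        "train": student.extract_features(data.train[0]),
        "validation": student.extract_features(data.validation[0]),
        "test": student.extract_features(data.test[0]),
    }
    tc = dataclasses.replace(cfg.train, seed=cfg.seed, epochs=cfg.sso_epochs)
    backbone_name = student.config.backbone_name
    cache: dict[tuple, float] = {}
    n_evals = 0

    def train_heads(solution) -> FusionClassifier:
        config = decode_solution(tuple(int(v) for v in solution),
                                 backbone_name=backbone_name)
        model = FusionClassifier(config, input_shape=student.input_shape,
                                 n_tabular=student.n_tabular, seed=cfg.seed,
                                 backbone=student.backbone, freeze_backbone=True)
        model.fit((feats["train"], data.train[1], data.train[2]),
                  (feats["validation"], data.validation[1], data.validation[2]),
                  tc, features=True)
        return model

    def fitness(solution):
        nonlocal n_evals
        key = tuple(int(v) for v in solution)
        if key not in cache:
            n_evals += 1
            model = train_heads(key)
            pred = model.predict_features(feats["validation"], data.validation[1])
            cache[key] = float(np.mean(pred == data.validation[2]))
        return cache[key]

    params = dataclasses.replace(cfg.sso_params, seed=cfg.seed)
    state = sso.sso_optimize(fitness, SOLUTION_BOUNDS, params)

    final_model = train_heads(tuple(state.G))
    proba = final_model.predict_proba_features(feats["test"], data.test[1])
    pred = (proba >= 0.5).astype(int)
    metrics = evaluation.confusion_and_metrics(data.test[2], pred)
    metrics.auc = evaluation.auc(data.test[2], proba)
    compression = evaluation.compression_rate(
        stage1.selected_teacher.parameter_count, final_model.parameter_count)
    return Stage2Result(
        best_solution=tuple(int(v) for v in state.G),
        best_fitness=state.gbest,
        history=list(state.history),
        final_config=final_model.config,
        test_metrics=metrics,
        test_accuracy=metrics.accuracy,
        compression_pct=compression,
        n_fitness_evaluations=n_evals,
    )


def load_config(path: str) -> WorkflowConfig:
    """Build a WorkflowConfig from a YAML (or JSON) file.

    Top-level keys mirror the dataclass fields; nested sections
    (``synthetic``, ``preprocess``, ``train``, ``kd``, ``sso_params``) are
    passed as keyword arguments to the corresponding config dataclass.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    sections = {
        "synthetic": SyntheticSpec,
        "preprocess": PreprocessConfig,
        "train": TrainConfig,
        "kd": KDConfig,
        "sso_params": sso.SSOParams,
    }
    for key, value in raw.items():
        if key in sections:
            if key == "preprocess" and "target_shape" in value:
                value = dict(value, target_shape=tuple(value["target_shape"]))
            kwargs[key] = sections[key](**value)
        elif key in ("teachers", "students"):
            kwargs[key] = {name: (spec[0], tuple(spec[1]))
                           for name, spec in value.items()}
        else:
            kwargs[key] = value
    return WorkflowConfig(**kwargs)


def _config_hash(cfg: WorkflowConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(cfg: WorkflowConfig) -> dict:
    """Full two-stage run; returns a manifest of results sufficient to
    reproduce the run (config hash, seed, stage summaries)."""
    stage1 = run_stage1(cfg)
    stage2 = run_stage2(cfg, stage1)
    return {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stage1": {
            "selected_pair": list(stage1.selected_pair),
            "student_test_accuracy": stage1.student_test_accuracy,
            "fallback_used": stage1.fallback_used,
            "mean_delta_pct": stage1.report.attrs["mean_delta_pct"],
        },
        "stage2": {
            "best_solution": list(stage2.best_solution),
            "best_fitness": stage2.best_fitness,
            "test_accuracy": stage2.test_accuracy,
            "compression_pct": stage2.compression_pct,
            "test_metrics": stage2.test_metrics.to_dict(),
        },
    }
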