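"""End-to-end seeded benchmark runs used for validation and reporting.

One run generates a balanced six-class dataset, preprocesses it, makes the
stratified 60/40 split, grid-searches the three classification tasks on
the training partition, and evaluates each winning model on the untouched
hold-out.  A trajectory run trains the bone-vs-soft model the same way and
applies it to the four default in vivo drilling plans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import confusion, metrics
from .model import (GridConfig, TASKS, grid_search, predict,
                    split_train_holdout, stack_fingerprints)
from .preprocess import PreprocessParams, preprocess_dataset
from .synth import GeneratorConfig, generate_dataset, generate_trajectory, in_vivo_plans
from .trajectory import classify_trajectory


@dataclass
class TaskResult:
    task: str
    holdout_accuracy: float
    holdout_sensitivity: dict
    train_accuracy: float
    chosen_C1: float
    chosen_C2: float
    n_features: int
    top_wavenumber: float
    surviving_feature_sizes: list[int]
    model: object = field(repr=False, default=None)


@dataclass
class BenchmarkRun:
    seed: int
    n_train: int
    n_holdout: int
    tasks: dict[str, TaskResult]


def run_benchmark(seed: int, n_per_class: int = 27,
                  config: GeneratorConfig | None = None,
                  grid: GridConfig | None = None,
                  tasks: tuple[str, ...] = ("I", "II", "III"),
                  params: PreprocessParams | None = None) -> BenchmarkRun:
    """Generate, preprocess, split, grid-search and evaluate one seed."""
    config = config or GeneratorConfig()
    dataset = generate_dataset(n_per_class=n_per_class, config=config, seed=seed)
    fps = preprocess_dataset(dataset.acquisitions, params=params)
    X, y = stack_fingerprints(fps)
    tr, ho = split_train_holdout(y, seed=seed)

    results: dict[str, TaskResult] = {}
    for name in tasks:
        task = TASKS[name]
        grid_t = grid or GridConfig(seed=seed)
        mtr, ytr = task.apply(y[tr])
        mho, yho = task.apply(y[ho])
        res = grid_search(X[tr][mtr], ytr, task, grid_t, axis=dataset.axis)
        model = res.model

        pred_tr, _ = predict(model, X[tr][mtr])
        pred_ho, _ = predict(model, X[ho][mho])
        cm_tr = confusion(ytr, pred_tr, task.classes, phase="training-validation")
        cm_ho = confusion(yho, pred_ho, task.classes, phase="testing")
        m_tr, m_ho = metrics(cm_tr), metrics(cm_ho)
        results[name] = TaskResult(
            task=name,
            holdout_accuracy=m_ho["accuracy"],
            holdout_sensitivity=m_ho["sensitivity"],
            train_accuracy=m_tr["accuracy"],
            chosen_C1=model.C1, chosen_C2=model.C2,
            n_features=len(model.features),
            top_wavenumber=model.features.top_wavenumber,
            surviving_feature_sizes=res.surviving_feature_sizes,
            model=model)
    return BenchmarkRun(seed=seed, n_train=tr.size, n_holdout=ho.size,
                        tasks=results)


@dataclass
class TrajectoryRunResult:
    true_breaches: list[float]
    detected_breaches: list[float | None]

    @property
    def n_detected_within_1mm(self) -> int:
        return sum(1 for t, d in zip(self.true_breaches, self.detected_breaches)
                   if d is not None and abs(d - t) <= 1.0)


def run_trajectory_benchmark(model, seed: int,
                             config: GeneratorConfig | None = None,
                             params: PreprocessParams | None = None
                             ) -> TrajectoryRunResult:
    """Apply a trained binary model to the four default in vivo plans."""
    config = config or GeneratorConfig()
    children = np.random.SeedSequence(seed).spawn(4)
    true_b, det_b = [], []
    for plan, child in zip(in_vivo_plans(), children):
        traj = generate_trajectory(plan, config=config,
                                   seed=int(child.generate_state(1)[0] % 2**31))
        report = classify_trajectory(model, traj, params=params)
        true_b.append(traj.breach_depth)
        det_b.append(report.detected_breach_depth)
    return TrajectoryRunResult(true_breaches=true_b, detected_breaches=det_b)


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    """Derive *n* independent 31-bit run seeds from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


@dataclass
class ProtocolSummary:
    """Aggregates of the repeated-seed benchmark protocol."""

    seeds: list[int]
    accuracy_six_class: list[float]     # hold-out, task I, per seed
    accuracy_bone_vs_soft: list[float]  # hold-out, task III, per seed
    sensitivity_cord: list[float]       # task II positive-class, per seed
    sensitivity_soft: list[float]       # task III positive-class, per seed
    max_feature_count: int              # over every surviving CV candidate
    top_band_centers: list[float]       # task III top-weight bin's band
    breaches_true: int
    breaches_detected_within_1mm: int

    @property
    def majority_band_center(self) -> float:
        vals, counts = np.unique(np.array(self.top_band_centers),
                                 return_counts=True)
        return float(vals[np.argmax(counts)])


def run_protocol(base_seed: int, n_seeds: int = 10, n_per_class: int = 27,
                 config: GeneratorConfig | None = None) -> ProtocolSummary:
    """The repeated-seed study: ten independent datasets, three tasks each,
    plus breach detection with the bone-vs-soft model on the four default
    in vivo trajectories per seed."""
    from .bands import find_band

    seeds = spawn_seeds(base_seed, n_seeds)
    acc_i, acc_iii, sens_ii, sens_iii, tops = [], [], [], [], []
    max_feat, br_true, br_hit = 0, 0, 0
    for seed in seeds:
        run = run_benchmark(seed, n_per_class=n_per_class, config=config)
        r1, r2, r3 = run.tasks["I"], run.tasks["II"], run.tasks["III"]
        acc_i.append(r1.holdout_accuracy)
        acc_iii.append(r3.holdout_accuracy)
        sens_ii.append(r2.holdout_sensitivity["spinal_cord"])
        sens_iii.append(r3.holdout_sensitivity["soft"])
        for r in (r1, r2, r3):
            max_feat = max(max_feat, max(r.surviving_feature_sizes))
        tops.append(find_band(r3.top_wavenumber).representative)
        traj = run_trajectory_benchmark(r3.model, seed=seed, config=config)
        br_true += len(traj.true_breaches)
        br_hit += traj.n_detected_within_1mm
    return ProtocolSummary(
        seeds=seeds, accuracy_six_class=acc_i,
        accuracy_bone_vs_soft=acc_iii, sensitivity_cord=sens_ii,
        sensitivity_soft=sens_iii, max_feature_count=max_feat,
        top_band_centers=tops, breaches_true=br_true,
        breaches_detected_within_1mm=br_hit)
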