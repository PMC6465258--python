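"""End-to-end experiment designs on synthetic cohorts.

Three designs mirror how a marrow-texture SVM study is evaluated:

* kernel x feature-dimension sweep on a fixed training draw,
* training-size sweep with repeated random balanced subsets
  (highest / lowest / mean +- SD per size), whose mean accuracies feed
  the learning-curve fit,
* classifier-vs-reader comparison on a fixed held-out test set, with
  simulated ordinal reader scores so the reader statistics are
  exercisable without humans.

A single master seed determines every source of randomness (cohort
generation, CV folds, subset draws, reader simulation) through a
counter-based spawn-key scheme, so stages can run in any order and
reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, evaluate, featurize, learncurve, phantom, preprocess

__all__ = [
    "ExperimentConfig",
    "PipelineData",
    "SweepResult",
    "prepare_pipeline",
    "kernel_dimension_sweep",
    "training_size_sweep",
    "simulate_readers",
    "learning_points_from_sweep",
    "run_full_experiment",
    "StageError",
]

# spawn-key stage ids for the counter-based seed scheme
_STAGE_TRAIN_COHORT = 0
_STAGE_TEST_COHORT = 1
_STAGE_SUBSET = 2
_STAGE_FOLDS = 3
_STAGE_READERS = 4
_STAGE_FIG1_DRAW = 5


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one full experiment."""

    phantom: phantom.PhantomConfig = field(default_factory=phantom.PhantomConfig)
    n_train_control: int = 180
    n_train_diseased: int = 180
    n_test_control: int = 45
    n_test_diseased: int = 62
    kernels: tuple[str, ...] = ("poly3", "tanh", "rbf")
    slice_settings: tuple[int, ...] = (1, 3, 9)
    n_slices_final: int = 9
    fig1_train_size: int = 180
    training_sizes: tuple[int, ...] = (180, 240, 300, 360)
    repetitions: int = 30
    C_grid: tuple[float, ...] = classify.DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = classify.DEFAULT_GAMMA_GRID
    erosion_radius: int = 1
    growcut_max_iters: int = 200
    connectivity: int = 26
    # simulated reader operating points (sensitivity, specificity)
    reader_targets: tuple[tuple[float, float], ...] = ((0.82, 0.76), (0.84, 0.80))
    target_accuracy: float = 0.85
    master_seed: int = 0

    def validate(self) -> None:
        self.phantom.validate()
        n_train = self.n_train_control + self.n_train_diseased
        if self.training_sizes and max(self.training_sizes) > n_train:
            raise ValueError("training sizes exceed the available training cohort")
        if self.fig1_train_size > n_train:
            raise ValueError("fig1_train_size exceeds the training cohort")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    def seed_for(self, *key: int) -> int:
        """Deterministic child seed (< 2**31) for a stage/counter key."""
        state = np.random.SeedSequence(
            self.master_seed, spawn_key=tuple(key)
        ).generate_state(1)[0]
        return int(state) & 0x7FFFFFFF


@dataclass
class PipelineData:
    """Generated and preprocessed cohorts shared by the experiment designs."""

    train_records: list[phantom.SubjectRecord]
    test_records: list[phantom.SubjectRecord]
    train_norm: list[phantom.SpineVolume]
    test_norm: list[phantom.SpineVolume]
    train_masks: list[preprocess.MarrowMask]
    test_masks: list[preprocess.MarrowMask]

    @property
    def train_labels(self) -> np.ndarray:
        return np.array([r.disease_status for r in self.train_records])

    @property
    def test_labels(self) -> np.ndarray:
        return np.array([r.disease_status for r in self.test_records])


@dataclass
class SweepResult:
    """Per-condition records plus recomputable aggregates."""

    records: pd.DataFrame
    group_keys: tuple[str, ...]

    _METRICS = ("test_accuracy", "test_sensitivity", "test_specificity", "test_auc")

    def aggregate(self) -> pd.DataFrame:
        rows = []
        for keys, grp in self.records.groupby(list(self.group_keys)):
            if not isinstance(keys, tuple):
                keys = (keys,)
            row = dict(zip(self.group_keys, keys))
            for metric in self._METRICS:
                if metric not in grp:
                    continue
                vals = grp[metric].to_numpy()
                row[f"{metric}_highest"] = vals.max()
                row[f"{metric}_lowest"] = vals.min()
                row[f"{metric}_mean"] = vals.mean()
                row[f"{metric}_sd"] = vals.std(ddof=1) if vals.size > 1 else 0.0
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shared pipeline stages


def preprocess_subject(
    record: phantom.SubjectRecord,
    erosion_radius: int = 1,
    max_iters: int = 200,
    connectivity: int = 26,
) -> tuple[phantom.SpineVolume, preprocess.MarrowMask]:
    """Disk-normalize one subject and segment its marrow with GrowCut."""
    roi = preprocess.select_reference_disk(record.labels)
    norm = preprocess.normalize_by_disk(record.volume, roi)
    seeds = preprocess.auto_seeds(record.labels, erosion_radius)
    mask = preprocess.growcut_segment(
        norm, seeds, max_iters=max_iters, connectivity=connectivity
    )
    return norm, mask


def prepare_pipeline(config: ExperimentConfig) -> PipelineData:
    """Generate and preprocess the training pool and the fixed test set."""
    config.validate()
    train = phantom.generate_cohort(
        config.phantom,
        config.n_train_control,
        config.n_train_diseased,
        seed=config.seed_for(_STAGE_TRAIN_COHORT),
    )
    test = phantom.generate_cohort(
        config.phantom,
        config.n_test_control,
        config.n_test_diseased,
        seed=config.seed_for(_STAGE_TEST_COHORT),
    )
    # test subjects get distinct ids so manifests are unambiguous
    for rec in test:
        rec.subject_id = "T" + rec.subject_id
    train_out = [
        preprocess_subject(
            r, config.erosion_radius, config.growcut_max_iters, config.connectivity
        )
        for r in train
    ]
    test_out = [
        preprocess_subject(
            r, config.erosion_radius, config.growcut_max_iters, config.connectivity
        )
        for r in test
    ]
    return PipelineData(
        train_records=train,
        test_records=test,
        train_norm=[t[0] for t in train_out],
        test_norm=[t[0] for t in test_out],
        train_masks=[t[1] for t in train_out],
        test_masks=[t[1] for t in test_out],
    )


def _build_matrices(
    data: PipelineData, n_slices: int
) -> tuple[featurize.FeatureMatrix, featurize.FeatureMatrix]:
    """Unscaled train/test matrices at one slice setting.

    The minimal window is fitted on the whole subject population
    (train + test), a purely geometric quantity.
    """
    all_records = data.train_records + data.test_records
    all_masks = data.train_masks + data.test_masks
    spec = featurize.compute_min_window(all_records, all_masks, n_slices=n_slices)
    vecs_train = [
        featurize.extract_feature_vector(
            vol, rec.labels, spec, mask, rec.subject_id
        )
        for rec, vol, mask in zip(data.train_records, data.train_norm, data.train_masks)
    ]
    vecs_test = [
        featurize.extract_feature_vector(
            vol, rec.labels, spec, mask, rec.subject_id
        )
        for rec, vol, mask in zip(data.test_records, data.test_norm, data.test_masks)
    ]
    train_m = featurize.assemble_matrix(vecs_train, data.train_labels)
    test_m = featurize.assemble_matrix(vecs_test, data.test_labels)
    return train_m, test_m


def _subset(matrix: featurize.FeatureMatrix, idx: np.ndarray) -> featurize.FeatureMatrix:
    return featurize.FeatureMatrix(
        matrix.X[idx],
        matrix.y[idx],
        [matrix.subject_ids[i] for i in idx],
        scaled=matrix.scaled,
        col_min=matrix.col_min,
        col_max=matrix.col_max,
    )


def _balanced_draw(y: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Class-balanced random subset of row indices (size split half/half)."""
    n1 = size // 2
    n0 = size - n1
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if n0 > idx0.size or n1 > idx1.size:
        raise ValueError(f"subset size {size} exceeds per-class availability")
    pick = np.concatenate(
        [rng.choice(idx0, n0, replace=False), rng.choice(idx1, n1, replace=False)]
    )
    return np.sort(pick)


def _fit_and_test(
    train_m: featurize.FeatureMatrix,
    test_m: featurize.FeatureMatrix,
    kernel: str,
    C_grid,
    gamma_grid,
    fold_seed: int,
) -> dict:
    """Scale, grid-search, train, and evaluate one configuration."""
    train_s, [test_s] = featurize.minmax_scale(train_m, [test_m])
    gs = classify.grid_search_cv(
        train_s, kernel, C_grid=C_grid, gamma_grid=gamma_grid, seed=fold_seed
    )
    model = classify.train_svm(train_s, gs.best)
    pred_train = classify.predict(model, train_s)
    pred_test = classify.predict(model, test_s)
    train_rep = evaluate.confusion_metrics(pred_train.labels, train_s.y)
    test_rep = evaluate.confusion_metrics(pred_test.labels, test_s.y)
    test_auc, test_auc_ci = evaluate.roc_auc(pred_test.scores, test_s.y)
    train_auc, _ = evaluate.roc_auc(pred_train.scores, train_s.y)
    return {
        "kernel": kernel,
        "C": gs.best.C,
        "gamma": gs.best.gamma,
        "cv_accuracy": gs.best_accuracy,
        "n_support": model.n_support,
        "train_accuracy": train_rep.accuracy,
        "train_sensitivity": train_rep.sensitivity,
        "train_specificity": train_rep.specificity,
        "train_auc": train_auc,
        "test_accuracy": test_rep.accuracy,
        "test_sensitivity": test_rep.sensitivity,
        "test_specificity": test_rep.specificity,
        "test_auc": test_auc,
        "test_auc_ci_low": test_auc_ci[0],
        "test_auc_ci_high": test_auc_ci[1],
        "_scores": pred_test.scores,
        "_labels": pred_test.labels,
    }


def _public(row: dict) -> dict:
    return {k: v for k, v in row.items() if not k.startswith("_")}


# ---------------------------------------------------------------------------
# experiment designs


def kernel_dimension_sweep(
    config: ExperimentConfig, data: PipelineData | None = None
) -> SweepResult:
    """Kernel x slice-count sweep on one fixed balanced training draw."""
    config.validate()
    if data is None:
        data = prepare_pipeline(config)
    rng = np.random.default_rng(config.seed_for(_STAGE_FIG1_DRAW))
    draw = _balanced_draw(data.train_labels, config.fig1_train_size, rng)
    rows = []
    for si, n_slices in enumerate(config.slice_settings):
        train_m, test_m = _build_matrices(data, n_slices)
        train_sub = _subset(train_m, draw)
        for ki, kernel in enumerate(config.kernels):
            row = _fit_and_test(
                train_sub,
                test_m,
                kernel,
                config.C_grid,
                config.gamma_grid,
                fold_seed=config.seed_for(_STAGE_FOLDS, si, ki),
            )
            row["n_slices"] = n_slices
            row["dimension"] = train_m.dimension
            rows.append(_public(row))
    records = pd.DataFrame(rows)
    return SweepResult(records=records, group_keys=("kernel", "n_slices"))


def training_size_sweep(
    config: ExperimentConfig,
    data: PipelineData | None = None,
    kernel: str = "rbf",
) -> SweepResult:
    """Repeated random balanced subsets at each training size.

    Per size, ``repetitions`` independent draws are each grid-searched,
    trained, and evaluated on the fixed test set; per-repetition
    records allow every aggregate to be recomputed.
    """
    config.validate()
    if data is None:
        data = prepare_pipeline(config)
    train_m, test_m = _build_matrices(data, config.n_slices_final)
    rows = []
    for si, size in enumerate(config.training_sizes):
        for rep in range(config.repetitions):
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    config.master_seed, spawn_key=(_STAGE_SUBSET, si, rep)
                )
            )
            draw = _balanced_draw(data.train_labels, size, rng)
            row = _fit_and_test(
                _subset(train_m, draw),
                test_m,
                kernel,
                config.C_grid,
                config.gamma_grid,
                fold_seed=config.seed_for(_STAGE_FOLDS, 100 + si, rep),
            )
            row["training_size"] = size
            row["repetition"] = rep
            rows.append(_public(row))
    records = pd.DataFrame(rows)
    return SweepResult(records=records, group_keys=("training_size",))


def simulate_readers(
    truth,
    sensitivity_target: float,
    specificity_target: float,
    seed: int = 0,
) -> np.ndarray:
    """Ordinal 0-4 confidence scores hitting the requested operating point.

    Each diseased subject is called positive with probability
    ``sensitivity_target`` and each control negative with probability
    ``specificity_target``; positive calls draw confidence from {3, 4}
    and negative calls from {0, 1, 2}, with mass concentrated at the
    confident end so scores behave like a decisive reader.  Binarized
    (3-4 positive) scores therefore achieve the targets in expectation.
    """
    truth = np.asarray(truth, dtype=int)
    for name, p in (
        ("sensitivity_target", sensitivity_target),
        ("specificity_target", specificity_target),
    ):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"{name} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    scores = np.empty(truth.size, dtype=int)
    for i, t in enumerate(truth):
        if t == 1:
            positive = rng.uniform() < sensitivity_target
        else:
            positive = rng.uniform() >= specificity_target
        if positive:
            scores[i] = rng.choice([3, 4], p=[0.4, 0.6])
        else:
            scores[i] = rng.choice([0, 1, 2], p=[0.5, 0.35, 0.15])
    return scores


def learning_points_from_sweep(
    sweep: SweepResult, metric: str = "test_accuracy"
) -> list[learncurve.CurvePoint]:
    """Mean performance per training size as learning-curve points,
    anchored by a chance-level point at x = 0 (excluded from fitting)."""
    agg = sweep.aggregate().sort_values("training_size")
    pts = [learncurve.CurvePoint(x=0.0, y=0.5)]
    for _, row in agg.iterrows():
        pts.append(
            learncurve.CurvePoint(
                x=float(row["training_size"]), y=float(row[f"{metric}_mean"])
            )
        )
    return pts


# ---------------------------------------------------------------------------
# full run


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_full_experiment(config: ExperimentConfig, outdir) -> dict:
    """Execute simulate -> preprocess -> featurize -> sweeps -> evaluate ->
    learning curve, writing CSV/JSON reports and a JSON-lines log.

    Returns a bundle dict with the key results and output paths.
    Partial outputs are retained if a later stage fails.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "log.jsonl"
    bundle: dict = {"outdir": outdir}

    def log(stage: str, **kw) -> None:
        entry = {"stage": stage, "time": time.time(), **kw}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry, default=_json_default, sort_keys=True) + "\n")

    def run_stage(name: str, fn):
        try:
            out = fn()
            log(name, status="ok")
            return out
        except Exception as exc:
            log(name, status="failed", error=str(exc))
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), default=_json_default, indent=1)
    )
    log("config", master_seed=config.master_seed)

    data = run_stage("prepare", lambda: prepare_pipeline(config))

    fig1 = run_stage("kernel_dimension_sweep",
                     lambda: kernel_dimension_sweep(config, data))
    fig1.records.to_csv(outdir / "fig1_data.csv", index=False)
    bundle["fig1"] = fig1

    table1 = run_stage("training_size_sweep",
                       lambda: training_size_sweep(config, data))
    table1.records.to_csv(outdir / "table1_records.csv", index=False)
    table1.aggregate().to_csv(outdir / "table1.csv", index=False)
    bundle["table1"] = table1

    # learning curves for accuracy and sensitivity
    curves = {}
    for metric, name in (
        ("test_accuracy", "accuracy"),
        ("test_sensitivity", "sensitivity"),
    ):
        pts = learning_points_from_sweep(table1, metric)
        pd.DataFrame([dataclasses.asdict(p) for p in pts]).to_csv(
            outdir / f"fig3_points_{name}.csv", index=False
        )
        if len([p for p in pts if p.x > 0]) > 3:
            def fit_metric(pts=pts):
                return learncurve.fit_inverse_power(pts)
            try:
                fit, gof = run_stage(f"learncurve_{name}", fit_metric)
            except StageError:
                continue
            report = {
                "a": fit.a, "b": fit.b, "c": fit.c,
                "SSE": gof.SSE, "RMSE": gof.RMSE, "n": gof.n, "m": gof.m,
                "covariance": fit.covariance,
                "well_behaved": fit.well_behaved,
            }
            if fit.well_behaved and config.target_accuracy < fit.asymptote:
                report["required_size_for_target"] = learncurve.required_sample_size(
                    fit, config.target_accuracy
                )
            (outdir / f"learncurve_{name}.json").write_text(
                json.dumps(report, default=_json_default, indent=1)
            )
            curves[name] = (fit, gof)
    bundle["curves"] = curves

    # reader comparison on the fixed test set, largest training size
    def table2():
        train_m, test_m = _build_matrices(data, config.n_slices_final)
        row = _fit_and_test(
            train_m, test_m, "rbf", config.C_grid, config.gamma_grid,
            fold_seed=config.seed_for(_STAGE_FOLDS, 999),
        )
        truth = data.test_labels
        svm_pred = row["_labels"]
        svm_scores = row["_scores"]
        svm_rep = evaluate.confusion_metrics(svm_pred, truth)
        svm_auc, svm_auc_ci = evaluate.roc_auc(svm_scores, truth)
        rows = []
        svm_row = svm_rep.as_percent_row()
        svm_row.update({"who": "SVM", "AUC_value": svm_auc})
        rows.append(svm_row)
        for ri, (se_t, sp_t) in enumerate(config.reader_targets, start=1):
            scores = simulate_readers(
                truth, se_t, sp_t, seed=config.seed_for(_STAGE_READERS, ri)
            )
            calls = evaluate.binarize_scores(scores)
            rep = evaluate.confusion_metrics(calls, truth)
            auc, auc_ci = evaluate.roc_auc(scores.astype(float), truth)
            r = rep.as_percent_row()
            r.update(
                {
                    "who": f"Reader {ri}",
                    "AUC_value": auc,
                    "mcnemar_p_vs_svm": evaluate.mcnemar_test(
                        calls, svm_pred, truth
                    ),
                    "delong_p_vs_svm": evaluate.compare_auc(
                        scores.astype(float), svm_scores, truth
                    ),
                    "kappa_vs_svm": evaluate.cohen_kappa(calls, svm_pred).kappa,
                }
            )
            rows.append(r)
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "table2.csv", index=False)
        return {"df": df, "svm_report": svm_rep, "svm_auc": svm_auc,
                "svm_auc_ci": svm_auc_ci}

    bundle["table2"] = run_stage("reader_comparison", table2)
    log("done")
    return bundle
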