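"""SVM evaluation of the four component sets by repeated two-fold CV.

The evaluation protocol: extracted component vectors are standardized to
zero mean and unit variance *per vector* (across its K features --
standardization across the components, which for this pipeline coincide
with the samples they were extracted from), support-vector machines with
linear, RBF or polynomial kernels (C = 1 throughout; only kernel
hyper-parameters are searched) are trained on each of the four labelled
component sets, and performance is estimated by repeated stratified
two-fold cross-validation: each repetition splits the samples 50/50, each
half serves once as training and once as test set, and sensitivity /
specificity / accuracy are averaged within a repetition and then summarized
(mean and sd) over repetitions.

Two modes are provided. ``"nested"`` (default) selects the pipeline
configuration -- number of components M, SCP tolerance, penalty multiplier,
classifier, component set -- on an inner stratified two-fold split of each
training half, then refits the winner on the whole training half.
``"sweep"`` evaluates every grid cell on the outer folds and reports the
best cell, the mode used for fixed-parameter validation studies and for
producing full per-configuration tables.

With the default ``reference_policy="train_only"`` the class reference
profiles are averaged over training-fold samples only, so test-fold samples
never influence the features they are evaluated on.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .datasets import ExpressionDataset
from .decompose import SET_NAMES, extract_feature_sets
from .errors import LabelError, ScamixError
from .solver import SolverConfig

__all__ = [
    "ClassifierConfig", "CVGrid", "CVReport", "standardize_component",
    "confusion_metrics", "repeated_two_fold_cv", "grid_report",
    "default_classifier_grid",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """One SVM configuration; C is fixed at 1 by the protocol."""

    kernel: str = "linear"            # linear | rbf | polynomial
    C: float = 1.0
    rbf_sigma2: float | None = None   # kernel exp(-||x-y||^2 / (2 sigma^2))
    poly_degree: int | None = None

    def __post_init__(self):
        if self.kernel not in ("linear", "rbf", "polynomial"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel == "rbf" and (self.rbf_sigma2 is None or self.rbf_sigma2 <= 0):
            raise ValueError("rbf kernel needs a positive rbf_sigma2")
        if self.kernel == "polynomial" and (self.poly_degree is None
                                            or self.poly_degree < 2):
            raise ValueError("polynomial kernel needs poly_degree >= 2")

    def build(self) -> SVC:
        if self.kernel == "linear":
            return SVC(kernel="linear", C=self.C)
        if self.kernel == "rbf":
            return SVC(kernel="rbf", C=self.C, gamma=1.0 / (2.0 * self.rbf_sigma2))
        return SVC(kernel="poly", C=self.C, degree=self.poly_degree,
                   gamma="scale", coef0=1.0)

    def describe(self) -> str:
        if self.kernel == "rbf":
            return f"rbf(sigma2={self.rbf_sigma2:g})"
        if self.kernel == "polynomial":
            return f"polynomial(degree={self.poly_degree})"
        return "linear"


def default_classifier_grid(kernels=("linear", "rbf", "polynomial"),
                            rbf_sigma2_grid=tuple(np.arange(500.0, 1501.0, 100.0)),
                            poly_degrees=(2, 3, 4)) -> list[ClassifierConfig]:
    """The default classifier search grid (linear; RBF sigma^2 sweep; poly d)."""
    out = []
    for kernel in kernels:
        if kernel == "linear":
            out.append(ClassifierConfig("linear"))
        elif kernel == "rbf":
            out.extend(ClassifierConfig("rbf", rbf_sigma2=s) for s in rbf_sigma2_grid)
        else:
            out.extend(ClassifierConfig("polynomial", poly_degree=d)
                       for d in poly_degrees)
    return out


@dataclass
class CVGrid:
    """Search grids and protocol settings for repeated two-fold CV."""

    M_values: tuple = (2, 3, 4, 5)
    delta_theta_values: tuple = (1.0, 3.0, 5.0)
    lambda_multipliers: tuple = (1e-2, 1e-4, 1e-6)
    classifiers: tuple = (ClassifierConfig("linear"),)
    component_sets: tuple = SET_NAMES
    nonnegative: bool = False
    n_outer_repetitions: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("M_values", "delta_theta_values", "lambda_multipliers",
                     "classifiers", "component_sets"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.n_outer_repetitions < 1:
            raise ValueError("need at least one repetition")

    def param_cells(self):
        return list(itertools.product(self.M_values, self.delta_theta_values,
                                      self.lambda_multipliers))


@dataclass
class CVReport:
    """Summary of a repeated two-fold cross-validation run."""

    mean_sensitivity: float
    sd_sensitivity: float
    mean_specificity: float
    sd_specificity: float
    mean_accuracy: float
    sd_accuracy: float
    n_repetitions: int
    winning_config: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "CVReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def standardize_component(v: np.ndarray) -> np.ndarray:
    """Scale one extracted component vector to zero mean, unit variance.

    Population standard deviation; a constant vector maps to the zero
    vector (with a warning) rather than dividing by zero.
    """
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        warnings.warn("constant component vector standardized to zeros")
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _standardize_rows(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    out = np.zeros_like(mat, dtype=float)
    np.divide(mat - mean, sd, out=out, where=sd > 0)
    return out


def confusion_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) w.r.t. class 1 = disease."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if set(np.unique(y_true)) != {1, -1}:
        raise LabelError("y_true must contain both classes 1 and -1")
    tp = np.count_nonzero((y_true == 1) & (y_pred == 1))
    fn = np.count_nonzero((y_true == 1) & (y_pred != 1))
    tn = np.count_nonzero((y_true == -1) & (y_pred == -1))
    fp = np.count_nonzero((y_true == -1) & (y_pred != -1))
    return (tp / (tp + fn), tn / (tn + fp), (tp + tn) / len(y_true))


def _stratified_halves(labels: np.ndarray, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """50/50 split; each fold's class count is within one of the other's."""
    half_a, half_b = [], []
    for cls in (1, -1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ScamixError(
                f"class {cls} has {len(idx)} sample(s); two-fold CV needs >= 2")
        idx = rng.permutation(idx)
        cut = len(idx) // 2 + (len(idx) % 2 if cls == 1 else 0)
        half_a.extend(idx[:cut])
        half_b.extend(idx[cut:])
    return np.sort(np.array(half_a)), np.sort(np.array(half_b))


def _evaluate_fold(feature_sets, set_name, clf_cfg, train_idx, test_idx):
    z = _standardize_rows(feature_sets.sets[set_name])
    y = feature_sets.labels
    clf = clf_cfg.build()
    clf.fit(z[train_idx], y[train_idx])
    pred = clf.predict(z[test_idx])
    return confusion_metrics(y[test_idx], pred)


def _extract_cached(cache, dataset, cell, solver_kwargs, reference_policy,
                    train_ids, subset_idx=None):
    key = (cell, tuple(sorted(train_ids)))
    if key not in cache:
        m, dtheta, lam_mult = cell
        solver = SolverConfig(lambda_multiplier=lam_mult, **solver_kwargs)
        cache[key] = extract_feature_sets(
            dataset, m, dtheta, solver, reference_policy=reference_policy,
            train_ids=train_ids)
    return cache[key]


def repeated_two_fold_cv(dataset: ExpressionDataset, grid: CVGrid,
                         reference_policy: str = "train_only",
                         mode: str = "nested") -> CVReport:
    """Run the repeated (optionally nested) two-fold CV protocol.

    Returns a :class:`CVReport`; in ``"sweep"`` mode the per-configuration
    fold records are attached as ``report.grid_records`` for
    :func:`grid_report`.
    """
    if mode not in ("nested", "sweep"):
        raise ValueError(f"unknown mode {mode!r}")
    dataset.require_both_classes()
    solver_kwargs = {"nonnegative": grid.nonnegative}
    ids = np.array(dataset.sample_ids)
    seeds = np.random.SeedSequence(grid.seed).spawn(grid.n_outer_repetitions)

    records = []        # one row per (repetition, fold, config)
    rep_metrics = []    # repetition-level (sens, spec, acc) of the reported pipeline
    rep_winners = []
    for rep, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        half_a, half_b = _stratified_halves(dataset.labels, rng)
        cache = {}
        fold_metrics = []
        for train_idx, test_idx in ((half_a, half_b), (half_b, half_a)):
            train_ids = ids[train_idx]
            if mode == "nested":
                winner = _inner_select(dataset, grid, reference_policy,
                                       solver_kwargs, train_idx, rng)
                cells = [winner[:3]]
                combos = [winner[3:]]
            else:
                cells = grid.param_cells()
                combos = None
            for cell in cells:
                fs = _extract_cached(cache, dataset, cell, solver_kwargs,
                                     reference_policy, train_ids)
                pairs = combos if combos is not None else \
                    list(itertools.product(grid.component_sets, grid.classifiers))
                for set_name, clf_cfg in pairs:
                    sens, spec, acc = _evaluate_fold(fs, set_name, clf_cfg,
                                                     train_idx, test_idx)
                    records.append({
                        "repetition": rep, "M": cell[0], "delta_theta": cell[1],
                        "lambda_multiplier": cell[2],
                        "classifier": clf_cfg.describe(),
                        "component_set": set_name, "sensitivity": sens,
                        "specificity": spec, "accuracy": acc,
                    })
                    if mode == "nested":
                        fold_metrics.append((sens, spec, acc))
                        rep_winners.append(cell + (set_name, clf_cfg))
        if mode == "nested":
            rep_metrics.append(np.mean(fold_metrics, axis=0))

    if mode == "nested":
        win_cell = _modal(rep_winners)
        winning = _describe_config(win_cell[:3], win_cell[4], win_cell[3])
        rep_arr = np.array(rep_metrics)
    else:
        frame = pd.DataFrame.from_records(records)
        keys = ["M", "delta_theta", "lambda_multiplier", "classifier",
                "component_set"]
        per_rep = frame.groupby(keys + ["repetition"], sort=False).mean(
            numeric_only=True).reset_index()
        agg = per_rep.groupby(keys, sort=False)["accuracy"].mean()
        best_key = agg.idxmax()
        best = per_rep[np.logical_and.reduce(
            [per_rep[k] == v for k, v in zip(keys, best_key)])]
        winning = _describe_config(best_key[:3], ClassifierConfig, best_key[4])
        winning["classifier"] = best_key[3]
        rep_arr = best[["sensitivity", "specificity", "accuracy"]].to_numpy()

    mean = rep_arr.mean(axis=0)
    sd = rep_arr.std(axis=0, ddof=1) if len(rep_arr) > 1 else np.zeros(3)
    report = CVReport(
        mean_sensitivity=float(mean[0]), sd_sensitivity=float(sd[0]),
        mean_specificity=float(mean[1]), sd_specificity=float(sd[1]),
        mean_accuracy=float(mean[2]), sd_accuracy=float(sd[2]),
        n_repetitions=grid.n_outer_repetitions, winning_config=winning)
    report.grid_records = records
    return report


def _describe_config(cell, clf, set_name) -> dict:
    out = {"M": int(cell[0]), "delta_theta": float(cell[1]),
           "lambda_multiplier": float(cell[2]), "component_set": set_name}
    if isinstance(clf, ClassifierConfig):
        out["classifier"] = clf.describe()
    return out


def _modal(winners: list) -> tuple:
    counts = {}
    order = {}
    for i, w in enumerate(winners):
        key = (w[0], w[1], w[2], w[3], w[4].describe())
        counts[key] = counts.get(key, 0) + 1
        order.setdefault(key, (i, w))
    best = max(counts, key=lambda k: (counts[k], -order[k][0]))
    return order[best][1]


def _inner_select(dataset, grid, reference_policy, solver_kwargs,
                  train_idx, rng):
    """Pick (M, dtheta, lambda, set, classifier) on an inner two-fold split."""
    labels = dataset.labels[train_idx]
    for cls in (1, -1):
        if np.count_nonzero(labels == cls) < 2:
            raise ScamixError(
                f"inner split impossible: class {cls} has fewer than 2 "
                f"training samples")
    in_a, in_b = _stratified_halves(labels, rng)
    in_a, in_b = train_idx[in_a], train_idx[in_b]
    ids = np.array(dataset.sample_ids)
    cache = {}
    scores = {}
    first_seen = {}
    for fit_idx, val_idx in ((in_a, in_b), (in_b, in_a)):
        for cell in grid.param_cells():
            fs = _extract_cached(cache, dataset, cell, solver_kwargs,
                                 reference_policy, ids[fit_idx])
            for set_name, clf_cfg in itertools.product(grid.component_sets,
                                                       grid.classifiers):
                _, _, acc = _evaluate_fold(fs, set_name, clf_cfg,
                                           fit_idx, val_idx)
                key = cell + (set_name, clf_cfg)
                scores[key] = scores.get(key, 0.0) + acc
                first_seen.setdefault(key, len(first_seen))
    best = max(scores, key=lambda k: (scores[k], -first_seen[k]))
    return best


def grid_report(records) -> pd.DataFrame:
    """Full sweep table: mean metrics per configuration cell.

    ``records`` are the fold-level rows attached to a sweep-mode report
    (``report.grid_records``). Rows are ordered by decreasing accuracy.
    """
    if len(records) == 0:
        raise ScamixError("no configurations evaluated")
    frame = pd.DataFrame.from_records(records)
    keys = ["M", "delta_theta", "lambda_multiplier", "classifier", "component_set"]
    out = (frame.groupby(keys, sort=False)[["sensitivity", "specificity", "accuracy"]]
           .mean().reset_index())
    return out.sort_values("accuracy", ascending=False, kind="stable",
                           ignore_index=True)
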