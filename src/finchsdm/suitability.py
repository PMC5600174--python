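"""Presence/background boosted classification tree ensemble.

Sampling design (presence bootstrap + uniform background draw), model
fitting, tree-count selection by cross-validated deviance, accuracy
metrics, relative variable importance, partial dependence, averaged
prediction maps and area-by-suitability summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._boost import Booster, bernoulli_deviance, sigmoid
from .geodata import EnvStack, PREDICTOR_NAMES, RasterGrid

__all__ = [
    "BCTHyperParams",
    "SampleSet",
    "BCTModel",
    "BCTEnsemble",
    "sample_background",
    "bootstrap_presence",
    "fit_bct",
    "select_n_trees",
    "cv_auc",
    "auc_mann_whitney",
    "confusion_metrics",
    "variable_importance",
    "partial_dependence",
    "run_ensemble",
    "predict_map",
    "area_by_suitability",
    "equal_share_importance",
]


@dataclass(frozen=True)
class BCTHyperParams:
    """Boosting protocol parameters.

    Defaults follow the published protocol: learning rate 0.001, bag
    fraction 2/3, five splits per tree (<= 11 nodes), at least five samples
    per terminal node, trees added in steps of 50 with ten-fold
    cross-validated deviance and a patience of five steps.
    """

    learning_rate: float = 0.001
    bag_fraction: float = 2.0 / 3.0
    max_splits: int = 5
    min_leaf: int = 5
    tree_step: int = 50
    max_trees: int = 10_000
    patience: int = 5
    cv_folds: int = 10
    n_trees: int | None = None  # fixed tree count; skips CV selection


@dataclass
class SampleSet:
    """Balanced presence/background design matrix for one run."""

    features: np.ndarray  # n x 12
    labels: np.ndarray  # n, binary
    run_seed: int = 0
    feature_names: tuple[str, ...] = PREDICTOR_NAMES

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[0] != self.labels.size:
            raise ValueError("features and labels are inconsistent")
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values")

    @property
    def n(self) -> int:
        return self.labels.size


@dataclass
class BCTModel:
    """A fitted boosted classification tree model for one run."""

    booster: Booster
    n_trees: int
    feature_names: tuple[str, ...]
    sample: SampleSet
    cv_auc_: float | None = None
    cv_predictions_: tuple[np.ndarray, np.ndarray] | None = None  # (held-out proba, labels)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.booster.predict_proba(np.asarray(X, dtype=float))


@dataclass
class BCTEnsemble:
    """Averages over the randomized runs (Table-1 / Table-2 shape)."""

    models: list[BCTModel]
    metrics: pd.DataFrame  # rows: metric; cols: mean, sd, min, max
    importance: pd.DataFrame  # rows: variable; cols: mean, sd, min, max (percent)
    partial_dependence: dict[str, pd.DataFrame]  # variable -> (grid, mean curve, per-run curves)
    feature_names: tuple[str, ...]

    @property
    def n_runs(self) -> int:
        return len(self.models)


# ---------------------------------------------------------------------------
# Sampling design


def sample_background(
    stack: EnvStack,
    n: int,
    seed: int | None = None,
    exclude: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Uniform draw of ``n`` distinct background cells (without replacement).

    ``exclude`` is a (row, col) table of presence cells removed from the
    candidate pool (pass ``None`` to sample from all valid cells).
    """
    mask = stack.combined_nodata()
    valid = ~mask
    if exclude is not None and len(exclude):
        valid[exclude["row"].to_numpy(int), exclude["col"].to_numpy(int)] = False
    pool = np.flatnonzero(valid.ravel())
    if pool.size < n:
        raise ValueError(f"only {pool.size} candidate background cells, need {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool, size=n, replace=False)
    rows, cols = np.unravel_index(idx, stack.shape)
    x, y = stack.grid.cell_center(rows, cols)
    return pd.DataFrame({"row": rows, "col": cols, "x": x, "y": y})


def bootstrap_presence(presence: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Resample presence cells with replacement, preserving size."""
    if not len(presence):
        raise ValueError("need at least one presence cell")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(presence), size=len(presence))
    return presence.iloc[idx].reset_index(drop=True)


def build_sample_set(
    stack: EnvStack,
    presence: pd.DataFrame,
    background: pd.DataFrame,
    run_seed: int = 0,
    feature_names: tuple[str, ...] = PREDICTOR_NAMES,
) -> SampleSet:
    """Assemble the balanced labelled feature matrix for one run."""
    Xp = stack.feature_matrix(presence["row"].to_numpy(int), presence["col"].to_numpy(int), feature_names)
    Xb = stack.feature_matrix(background["row"].to_numpy(int), background["col"].to_numpy(int), feature_names)
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(len(Xp), dtype=int), np.zeros(len(Xb), dtype=int)])
    return SampleSet(X, y, run_seed=run_seed, feature_names=feature_names)


# ---------------------------------------------------------------------------
# Fitting and selection


def _check_sample(s: SampleSet) -> None:
    if s.n < 10:
        raise ValueError(f"need at least 10 samples, got {s.n}")
    if len(np.unique(s.labels)) < 2:
        raise ValueError("both classes must be present")


def fit_bct(s: SampleSet, hp: BCTHyperParams = BCTHyperParams(), n_trees: int | None = None,
            seed: int | None = None) -> BCTModel:
    """Fit one boosted model with a given or hp-fixed number of trees.

    If neither ``n_trees`` nor ``hp.n_trees`` is set, the count is chosen
    by :func:`select_n_trees` first.
    """
    _check_sample(s)
    if n_trees is None:
        n_trees = hp.n_trees
    if n_trees is None:
        n_trees, _, _ = select_n_trees(s, hp, seed=seed)
    booster = Booster(hp.learning_rate, hp.bag_fraction, hp.max_splits, hp.min_leaf,
                      rng=seed if seed is not None else s.run_seed)
    booster.fit(s.features, s.labels, n_trees)
    return BCTModel(booster, n_trees, s.feature_names, s)


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Index arrays of k stratified folds."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.sort(np.asarray(f)) for f in folds]


def select_n_trees(
    s: SampleSet, hp: BCTHyperParams = BCTHyperParams(), seed: int | None = None
) -> tuple[int, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Choose the tree count by stepped ten-fold CV deviance.

    Trees are added in steps of ``hp.tree_step``; mean held-out Bernoulli
    deviance across folds is tracked and growth stops when it has not
    improved for ``hp.patience`` consecutive steps (or at ``hp.max_trees``).

    Returns ``(n_trees, deviance_path, (heldout_proba, heldout_labels))``
    where the held-out probabilities are taken at the selected count and
    pooled over folds (the basis of the run's CV-AUC).
    """
    _check_sample(s)
    rng = np.random.default_rng(seed if seed is not None else s.run_seed)
    k = min(hp.cv_folds, int(np.min(np.bincount(s.labels.astype(int)))))
    folds = _stratified_folds(s.labels, k, rng)
    all_idx = np.arange(s.n)

    boosters, handles, test_sets = [], [], []
    for f in folds:
        train = np.setdiff1d(all_idx, f)
        b = Booster(hp.learning_rate, hp.bag_fraction, hp.max_splits, hp.min_leaf,
                    rng=rng.integers(2**31))
        b.init_data(s.features[train], s.labels[train])
        handles.append(b.track(s.features[f]))
        boosters.append(b)
        test_sets.append(f)

    deviances: list[float] = []
    snapshots: list[list[np.ndarray]] = []
    best_dev, best_step, step_i = np.inf, -1, 0
    while step_i * hp.tree_step < hp.max_trees:
        fold_probas = []
        dev_num = 0.0
        for b, h, f in zip(boosters, handles, test_sets):
            b.grow(hp.tree_step)
            p = b.tracked_proba(h)
            fold_probas.append(p.copy())
            dev_num += bernoulli_deviance(s.labels[f], p) * f.size
        dev = dev_num / s.n
        deviances.append(dev)
        snapshots.append(fold_probas)
        if dev < best_dev - 1e-12:
            best_dev, best_step = dev, step_i
        if step_i - best_step >= hp.patience:
            break
        step_i += 1

    n_trees = (best_step + 1) * hp.tree_step
    heldout = np.empty(s.n)
    for f, p in zip(test_sets, snapshots[best_step]):
        heldout[f] = p
    return n_trees, np.asarray(deviances), (heldout, s.labels.copy())


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def cv_auc(s: SampleSet, hp: BCTHyperParams = BCTHyperParams(), k: int = 10,
           seed: int | None = None, n_trees: int | None = None) -> float:
    """Stratified k-fold CV AUC on pooled held-out predictions."""
    _check_sample(s)
    counts = np.bincount(s.labels.astype(int))
    if counts.min() < k:
        raise ValueError(f"need at least {k} samples per class for {k}-fold CV")
    if n_trees is None:
        n_trees = hp.n_trees
    if n_trees is None:
        n_trees, _, _ = select_n_trees(s, hp, seed=seed)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(s.labels, k, rng)
    all_idx = np.arange(s.n)
    heldout = np.empty(s.n)
    for f in folds:
        train = np.setdiff1d(all_idx, f)
        b = Booster(hp.learning_rate, hp.bag_fraction, hp.max_splits, hp.min_leaf,
                    rng=rng.integers(2**31))
        b.fit(s.features[train], s.labels[train], n_trees)
        heldout[f] = b.predict_proba(s.features[f])
    return auc_mann_whitney(heldout, s.labels)


def confusion_metrics(pred: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    """Sensitivity, specificity, NPV and PPV at a probability threshold."""
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")
    pos = pred >= threshold
    tp = int(np.sum(pos & (labels == 1)))
    fn = int(np.sum(~pos & (labels == 1)))
    fp = int(np.sum(pos & (labels == 0)))
    tn = int(np.sum(~pos & (labels == 0)))

    def _ratio(a, b):
        return a / b if b else np.nan

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "npv": _ratio(tn, tn + fn),
        "ppv": _ratio(tp, tp + fp),
    }


def variable_importance(m: BCTModel) -> np.ndarray:
    """Relative influence per variable: summed split improvements, normalized to 100."""
    raw = m.booster.raw_importance(len(m.feature_names), m.n_trees)
    total = raw.sum()
    if total <= 0:
        return np.zeros_like(raw)
    return 100.0 * raw / total


def partial_dependence(
    model: "BCTModel | BCTEnsemble",
    variable: str,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial-dependence curve on the probability scale.

    For each grid value the variable is overwritten in every training row
    and the model probabilities are averaged.  For an ensemble, per-run
    curves (each on its own training rows) are averaged on a common grid.
    """
    if isinstance(model, BCTEnsemble):
        if variable not in model.feature_names:
            raise KeyError(f"unknown variable {variable!r}")
        if grid is None:
            lo = min(m.sample.features[:, model.feature_names.index(variable)].min() for m in model.models)
            hi = max(m.sample.features[:, model.feature_names.index(variable)].max() for m in model.models)
            grid = np.linspace(lo, hi, n_grid)
        curves = [partial_dependence(m, variable, grid)[1] for m in model.models]
        return np.asarray(grid), np.mean(curves, axis=0)

    if variable not in model.feature_names:
        raise KeyError(f"unknown variable {variable!r}")
    j = model.feature_names.index(variable)
    X = model.sample.features
    if grid is None:
        grid = np.linspace(X[:, j].min(), X[:, j].max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    curve = np.empty(grid.size)
    for i, v in enumerate(grid):
        Xi = X.copy()
        Xi[:, j] = v
        curve[i] = model.predict_proba(Xi).mean()
    return grid, curve


# ---------------------------------------------------------------------------
# The randomized-runs ensemble

_METRIC_ORDER = ["n_trees", "cv_auc", "sensitivity", "specificity", "npv", "ppv"]


def run_ensemble(
    stack: EnvStack,
    presences: pd.DataFrame,
    hp: BCTHyperParams = BCTHyperParams(),
    n_runs: int = 20,
    master_seed: int = 0,
    exclude_presence_background: bool = True,
    pd_variables: Sequence[str] | None = None,
    pd_grid_points: int = 100,
    threshold: float = 0.5,
) -> BCTEnsemble:
    """Repeat the model over randomized runs and average everything.

    Each run draws a fresh presence bootstrap and a fresh uniform
    background sample of equal size, selects its tree count by CV deviance
    (unless ``hp.n_trees`` fixes it), and contributes accuracy metrics,
    importance and partial dependence.  All randomness derives from
    ``master_seed`` via spawned seed sequences.
    """
    ss = np.random.SeedSequence(master_seed)
    run_seeds = ss.spawn(n_runs)
    names = tuple(PREDICTOR_NAMES)
    models: list[BCTModel] = []
    metric_rows: list[dict[str, float]] = []
    importance_rows: list[np.ndarray] = []

    for run, rs in enumerate(run_seeds):
        boot_seed, bg_seed, fit_seed = rs.spawn(3)
        pres = bootstrap_presence(presences, seed=boot_seed)
        bg = sample_background(
            stack, len(presences), seed=bg_seed,
            exclude=presences if exclude_presence_background else None,
        )
        s = build_sample_set(stack, pres, bg, run_seed=run, feature_names=names)

        fit_rng = np.random.default_rng(fit_seed)
        if hp.n_trees is None:
            n_trees, _, (heldout, held_labels) = select_n_trees(s, hp, seed=fit_rng.integers(2**31))
            run_auc = auc_mann_whitney(heldout, held_labels)
        else:
            n_trees = hp.n_trees
            run_auc = cv_auc(s, hp, k=min(hp.cv_folds, 10), seed=fit_rng.integers(2**31), n_trees=n_trees)

        model = fit_bct(s, hp, n_trees=n_trees, seed=int(fit_rng.integers(2**31)))
        model.cv_auc_ = run_auc
        models.append(model)

        train_pred = model.predict_proba(s.features)
        cm = confusion_metrics(train_pred, s.labels, threshold)
        metric_rows.append({"n_trees": n_trees, "cv_auc": run_auc, **cm})
        importance_rows.append(variable_importance(model))

    mdf = pd.DataFrame(metric_rows)[_METRIC_ORDER]
    metrics = pd.DataFrame(
        {"mean": mdf.mean(), "sd": mdf.std(ddof=1) if n_runs > 1 else 0.0,
         "min": mdf.min(), "max": mdf.max()}
    )
    idf = pd.DataFrame(importance_rows, columns=list(names))
    importance = pd.DataFrame(
        {"mean": idf.mean(), "sd": idf.std(ddof=1) if n_runs > 1 else 0.0,
         "min": idf.min(), "max": idf.max()}
    ).sort_values("mean", ascending=False)

    ens = BCTEnsemble(models, metrics, importance, {}, names)
    if pd_variables is None:
        pd_variables = list(importance.index[:4])
    for var in pd_variables:
        grid, curve = partial_dependence(ens, var, n_grid=pd_grid_points)
        percurve = {f"run_{i}": partial_dependence(m, var, grid)[1] for i, m in enumerate(models)}
        ens.partial_dependence[var] = pd.DataFrame({"grid": grid, "mean": curve, **percurve})
    return ens


def predict_map(e: "BCTEnsemble | BCTModel", stack: EnvStack) -> RasterGrid:
    """Averaged per-cell probability surface; nodata propagates."""
    models = e.models if isinstance(e, BCTEnsemble) else [e]
    names = models[0].feature_names
    mask = stack.combined_nodata()
    rows, cols = np.nonzero(~mask)
    X = stack.feature_matrix(rows, cols, names)
    pred = np.mean([m.predict_proba(X) for m in models], axis=0)
    out = np.full(stack.shape, np.nan)
    out[rows, cols] = pred
    g = stack.grid
    return RasterGrid(out, g.cell_size, g.origin, mask.copy())


def area_by_suitability(
    suit: RasterGrid,
    breaks: Sequence[float] = (0.0, 0.2, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0),
    thresholds: Sequence[float] = (0.5, 0.7, 0.8),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Area (ha and km^2) per suitability class and above thresholds.

    Classes are ``[b0, b1), [b1, b2), ..., [b_{k-1}, b_k]`` and partition
    the break span; areas are cell counts times cell area.
    """
    breaks = np.asarray(sorted(breaks), dtype=float)
    vals = suit.valid_values()
    if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
        raise ValueError("suitability map must lie in [0, 1]")
    counts, _ = np.histogram(vals, bins=breaks)
    cell_area_m2 = suit.cell_size**2
    classes = pd.DataFrame({
        "lower": breaks[:-1],
        "upper": breaks[1:],
        "n_cells": counts,
        "area_ha": counts * cell_area_m2 / 1e4,
        "area_km2": counts * cell_area_m2 / 1e6,
    })
    thr_rows = []
    for t in thresholds:
        n = int((vals > t).sum())
        thr_rows.append({"threshold": t, "n_cells": n,
                         "area_ha": n * cell_area_m2 / 1e4,
                         "area_km2": n * cell_area_m2 / 1e6})
    return classes, pd.DataFrame(thr_rows)


def equal_share_importance(n_predictors: int = 12) -> float:
    """Relative importance (%) expected per predictor under equal allocation."""
    if n_predictors < 1:
        raise ValueError("n_predictors must be positive")
    return 100.0 / n_predictors
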