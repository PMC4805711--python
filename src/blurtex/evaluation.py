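"""Experimental harness: blur-prediction error tables and the
train-clean / evaluate-degraded classification grid.

The grid protocol mirrors the equalization framework's study design: a
clean training set "A", a separate evaluation set "B" degraded at several
levels, decile thresholds taken from the *undegraded* evaluation set's blur
scores (reproduction mode; a switch derives them from the training set for
deployment settings where clean evaluation images are unavailable), and a
linear support vector classifier with unit regularization on train-set
standardized features.  Degenerate or non-converged images are never
dropped -- they stay in their set and are tallied per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .data import TextureDataset
from .descriptors import DESCRIPTORS
from .equalize import equalize_schedule, ideal_equalize
from .image import DegradationSpec, degrade
from .measures import DegenerateImageError, compute_thresholds, get_measure
from .synthetic import gaussian_levels

__all__ = [
    "PredictionErrorTable",
    "ExperimentGrid",
    "blur_prediction_error",
    "run_experiment",
    "best_theta_curve",
    "ideal_sigma_curve",
]

_MAX_PAIRS = 10_000


@dataclass
class PredictionErrorTable:
    """Pairwise blur-prediction error rates per base blur level.

    For each base sigma, ordered pairs (X at sigma, Y at sigma+step) are
    formed within a class (``mode="intra"``) or across classes ("inter");
    a prediction is correct when the oriented score of the stronger-blurred
    version is larger.  Ties split deterministically at half weight, so a
    constant scorer lands at the 0.5 guessing anchor.
    """

    mode: str
    measure_id: str
    table: pd.DataFrame  # columns: base_sigma, error_rate, n_pairs, n_skipped

    @property
    def mean_error(self) -> float:
        return float(self.table["error_rate"].mean())


def _pair_indices(labels: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    same = labels[:, None] == labels[None, :]
    if mode == "intra":
        mask = same
    elif mode == "inter":
        mask = ~same
    else:
        raise ValueError("mode must be 'intra' or 'inter'")
    np.fill_diagonal(mask, False)
    return np.nonzero(mask)


def score_table(
    dataset: TextureDataset, measure, sigmas: Iterable[float]
) -> dict[float, np.ndarray]:
    """Oriented blur scores of every image at each Gaussian level (NaN when
    the measure is degenerate on an image)."""
    _, fn = get_measure(measure)
    out = {}
    for s in sigmas:
        spec = DegradationSpec("gaussian", sigma=float(s))
        vals = np.empty(len(dataset))
        for i, img in enumerate(dataset.images):
            try:
                vals[i] = fn(degrade(img, spec)).value
            except DegenerateImageError:
                vals[i] = np.nan
        out[float(s)] = vals
    return out


def blur_prediction_error(
    dataset: TextureDataset,
    measure,
    mode: str = "intra",
    sigma_step: float = 0.5,
    max_base_sigma: float = 3.5,
    max_pairs: int = _MAX_PAIRS,
    seed: int = 0,
    scores: dict[float, np.ndarray] | None = None,
) -> PredictionErrorTable:
    """Error of deciding which of two textures is stronger blurred.

    Pairs are exhaustive when at most ``max_pairs`` exist for a base level,
    otherwise a seeded subsample of ``max_pairs`` is drawn.  A precomputed
    ``scores`` table (from :func:`score_table`) can be supplied to avoid
    re-measuring the same degraded images across calls.
    """
    if dataset.n_classes < 2:
        raise ValueError("dataset must contain at least 2 classes")
    mid, _ = get_measure(measure)
    bases = np.arange(0.0, max_base_sigma + sigma_step / 2, sigma_step)
    needed = sorted({float(s) for s in bases} | {float(s + sigma_step) for s in bases})
    if scores is None:
        scores = score_table(dataset, measure, needed)
    ii, jj = _pair_indices(dataset.labels, mode)
    rows = []
    for k, base in enumerate(bases):
        s_lo = scores[float(base)][ii]
        s_hi = scores[round(float(base + sigma_step), 10)][jj]
        ok = np.isfinite(s_lo) & np.isfinite(s_hi)
        n_skipped = int((~ok).sum())
        lo, hi = s_lo[ok], s_hi[ok]
        if lo.size > max_pairs:
            rng = np.random.default_rng([seed, k])
            pick = rng.choice(lo.size, size=max_pairs, replace=False)
            lo, hi = lo[pick], hi[pick]
        # correct iff the blurrier version scores strictly higher; ties 1/2
        correct = np.where(hi > lo, 1.0, np.where(hi == lo, 0.5, 0.0))
        rows.append(
            {
                "base_sigma": float(base),
                "error_rate": float(1.0 - correct.mean()) if lo.size else np.nan,
                "n_pairs": int(lo.size),
                "n_skipped": n_skipped,
            }
        )
    return PredictionErrorTable(mode, mid, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Classification grid
# ---------------------------------------------------------------------------

def fit_and_score(train_X, train_y, eval_X, eval_y) -> float:
    """Linear max-margin classifier (C = 1, one-vs-rest) on train-standardized
    features; returns evaluation accuracy."""
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", LinearSVC(C=1.0, dual=False, tol=1e-5, max_iter=20_000, random_state=0)),
        ]
    )
    clf.fit(np.asarray(train_X), np.asarray(train_y))
    return float(clf.score(np.asarray(eval_X), np.asarray(eval_y)))


@dataclass
class ExperimentGrid:
    """Long-format accuracy table.

    Columns: descriptor, measure, theta_index (0 for the unequalized
    baseline, with measure "none"), kind, level, accuracy, n_eval,
    n_nonconverged_train, n_nonconverged_eval, n_degenerate_train,
    n_degenerate_eval.
    """

    table: pd.DataFrame

    def accuracy(self, descriptor: str, kind: str, level: float,
                 measure: str = "none", theta_index: int = 0) -> float:
        t = self.table
        sel = t[
            (t.descriptor == descriptor)
            & (t.measure == measure)
            & (t.theta_index == theta_index)
            & (t.kind == kind)
            & (np.isclose(t.level, level))
        ]
        if len(sel) != 1:
            raise KeyError(
                f"no unique cell ({descriptor}, {measure}, theta {theta_index}, {kind} {level})"
            )
        return float(sel.accuracy.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")


def _features(images: Sequence[np.ndarray], descriptor_fn) -> np.ndarray:
    return np.stack([descriptor_fn(img) for img in images])


def _equalized_features(
    images: Sequence[np.ndarray],
    measure: str,
    thetas: Sequence[float],
    descriptor_fns: dict,
    step_sigma: float,
    step_size: int,
    max_iter: int,
):
    """Features of every image equalized at each theta, via one shared
    trajectory per image.  Returns ``feats[t][name]`` (n_images x dim),
    non-convergence counts per theta and the degenerate-image count."""
    feats = {t: {name: [] for name in descriptor_fns} for t in range(len(thetas))}
    nonconverged = np.zeros(len(thetas), dtype=int)
    degenerate = 0
    for img in images:
        try:
            results = equalize_schedule(
                img, measure, thetas, step_sigma, step_size, max_iter
            )
        except DegenerateImageError:
            degenerate += 1
            results = None
        # thresholds that stop at the same iteration count share one extraction
        by_steps: dict[int, dict] = {}
        for t in range(len(thetas)):
            if results is None:
                eq_img, steps = img, -1
            else:
                eq_img, steps = results[t].image, results[t].iterations
                if not results[t].converged:
                    nonconverged[t] += 1
            if steps not in by_steps:
                by_steps[steps] = {
                    name: fn(eq_img) for name, fn in descriptor_fns.items()
                }
            for name in descriptor_fns:
                feats[t][name].append(by_steps[steps][name])
    for t in feats:
        for name in feats[t]:
            feats[t][name] = np.stack(feats[t][name])
    return feats, nonconverged, degenerate


def run_experiment(
    train: TextureDataset,
    eval_clean: TextureDataset,
    descriptors: Sequence[str] = ("mrlbp",),
    measures: Sequence[str] = ("co",),
    degradations: Sequence[DegradationSpec] | None = None,
    theta_quantiles: Sequence[int] = tuple(range(1, 11)),
    theta_source: str = "eval",
    step_sigma: float = 1.0,
    step_size: int = 3,
    max_iter: int = 64,
    include_baseline: bool = True,
) -> ExperimentGrid:
    """Train-clean / evaluate-degraded accuracy grid.

    For every (descriptor, measure, theta decile, degradation level) cell
    both the training set and the degraded evaluation set are equalized at
    theta before feature extraction; baseline cells (theta_index 0) skip
    equalization.  Thresholds come from the undegraded evaluation set's
    scores (``theta_source="eval"``, the reproduction protocol) or from the
    training set ("train", the deployment protocol).
    """
    if sorted(set(train.class_names)) != sorted(set(eval_clean.class_names)):
        raise ValueError("train and evaluation class sets do not match")
    if degradations is None:
        degradations = gaussian_levels()
    descriptor_fns = {}
    for name in descriptors:
        if name not in DESCRIPTORS:
            raise ValueError(f"unknown descriptor {name!r}")
        descriptor_fns[name] = DESCRIPTORS[name]
    theta_quantiles = list(theta_quantiles)

    rows = []
    eval_sets = [(spec, [degrade(img, spec) for img in eval_clean.images]) for spec in degradations]

    if include_baseline:
        base_train = {n: _features(train.images, f) for n, f in descriptor_fns.items()}
        for spec, imgs in eval_sets:
            for name in descriptor_fns:
                acc = fit_and_score(
                    base_train[name], train.labels,
                    _features(imgs, descriptor_fns[name]), eval_clean.labels,
                )
                rows.append(
                    dict(
                        descriptor=name, measure="none", theta_index=0,
                        kind=spec.kind if not spec.is_identity else spec.kind,
                        level=spec.level, accuracy=acc, n_eval=len(imgs),
                        n_nonconverged_train=0, n_nonconverged_eval=0,
                        n_degenerate_train=0, n_degenerate_eval=0,
                    )
                )

    for measure in measures:
        mid, fn = get_measure(measure)
        source = eval_clean if theta_source == "eval" else train
        ref_scores = []
        for img in source.images:
            try:
                ref_scores.append(fn(img))
            except DegenerateImageError:
                continue
        thresholds = compute_thresholds(ref_scores, mid)
        thetas = [thresholds.theta(q) for q in theta_quantiles]

        train_feats, train_nc, train_deg = _equalized_features(
            train.images, mid, thetas, descriptor_fns, step_sigma, step_size, max_iter
        )
        for spec, imgs in eval_sets:
            ev_feats, ev_nc, ev_deg = _equalized_features(
                imgs, mid, thetas, descriptor_fns, step_sigma, step_size, max_iter
            )
            for t, q in enumerate(theta_quantiles):
                for name in descriptor_fns:
                    acc = fit_and_score(
                        train_feats[t][name], train.labels,
                        ev_feats[t][name], eval_clean.labels,
                    )
                    rows.append(
                        dict(
                            descriptor=name, measure=mid, theta_index=int(q),
                            kind=spec.kind, level=spec.level, accuracy=acc,
                            n_eval=len(imgs),
                            n_nonconverged_train=int(train_nc[t]),
                            n_nonconverged_eval=int(ev_nc[t]),
                            n_degenerate_train=train_deg,
                            n_degenerate_eval=ev_deg,
                        )
                    )
    return ExperimentGrid(pd.DataFrame(rows))


def best_theta_curve(grid: ExperimentGrid) -> pd.DataFrame:
    """Best accuracy over theta per (descriptor, measure, level), with the
    unequalized baseline joined for comparison."""
    t = grid.table
    eq = t[t.theta_index > 0]
    if eq.empty:
        raise ValueError("grid contains no equalized cells")
    best = (
        eq.groupby(["descriptor", "measure", "kind", "level"], as_index=False)
        .accuracy.max()
        .rename(columns={"accuracy": "best_accuracy"})
    )
    base = t[t.theta_index == 0][["descriptor", "kind", "level", "accuracy"]].rename(
        columns={"accuracy": "baseline_accuracy"}
    )
    return best.merge(base, on=["descriptor", "kind", "level"], how="left")


def ideal_sigma_curve(
    train: TextureDataset,
    eval_clean: TextureDataset,
    descriptors: Sequence[str] = ("mrlbp",),
    sigma_levels: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0),
    target_sigmas: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Accuracy when equalization is driven by the *true* Gaussian sigma.

    Only meaningful on synthetic data where the evaluation blur is applied
    here, so every image's sigma is known by construction.  Both sets are
    brought to each target sigma via the semigroup rule (blur is only ever
    added: images already past the target pass through unchanged), then the
    standard classification protocol runs.
    """
    if target_sigmas is None:
        target_sigmas = sigma_levels
    descriptor_fns = {n: DESCRIPTORS[n] for n in descriptors}
    rows = []
    for tgt in target_sigmas:
        train_X = {
            n: _features([ideal_equalize(im, 0.0, tgt) for im in train.images], f)
            for n, f in descriptor_fns.items()
        }
        for s in sigma_levels:
            blurred = [degrade(im, DegradationSpec("gaussian", sigma=float(s)))
                       for im in eval_clean.images]
            ev = [ideal_equalize(im, float(s), tgt) for im in blurred]
            for n, f in descriptor_fns.items():
                acc = fit_and_score(train_X[n], train.labels, _features(ev, f), eval_clean.labels)
                rows.append(
                    dict(descriptor=n, level=float(s), target_sigma=float(tgt), accuracy=acc)
                )
    return pd.DataFrame(rows)
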