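"""Feature-subset selection with a naive-Bayes cross-validation fitness.

A candidate feature subset is encoded as a real-valued particle of length
``10 x (#bands)``; thresholding at 0 (strictly positive coordinates
select) decodes it into a 0/1 mask over the per-band feature blocks in
the canonical order STD, SAV, SDC, STA, SSHD, SCC, SSVL, CTM-0.3,
CTM-0.4, CTM-0.5.  The fitness of a mask is the mean stratified 10-fold
cross-validated accuracy of a Gaussian naive-Bayes classifier trained on
the selected columns (9:1 train/test split per fold); the optimizers of
:mod:`~sodpeeg.optimizers` maximize it.

Fold assignment is frozen per experiment and derived from a canonical
ordering of the samples (within-class lexicographic sort of the full
feature vectors followed by a seeded shuffle), so the fitness is a
deterministic function of the mask, invariant to row order, and identical
masks are never re-evaluated (results are memoized).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .optimizers import SwarmConfig, Trajectory, optimize
from .sodp_features import GEO_FEATURE_NAMES

__all__ = [
    "BAND_COMBINATIONS",
    "FeatureMask",
    "NBModel",
    "SelectionResult",
    "decode_mask",
    "nb_fit",
    "nb_predict",
    "stratified_folds",
    "feature_matrix",
    "cv_fitness",
    "select_features",
    "band_cross_experiment",
]

_BANDS = ("delta", "theta", "alpha", "beta")

#: The 15 band combinations studied, each in canonical band order.
BAND_COMBINATIONS = tuple(
    combo
    for r in range(1, 5)
    for combo in itertools.combinations(_BANDS, r)
)


@dataclass(frozen=True)
class FeatureMask:
    """A 0/1 feature-selection mask over concatenated band blocks."""

    bits: tuple[int, ...]
    bands: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != 10 * len(self.bands):
            raise ValueError("mask length must be 10 bits per band")
        if any(b not in _BANDS for b in self.bands):
            raise ValueError(f"bands must be among {_BANDS}")

    @property
    def n_selected(self) -> int:
        return int(sum(self.bits))

    def selected_names(self) -> list[str]:
        """Selected features as ``band:NAME`` strings."""
        names = []
        for i, bit in enumerate(self.bits):
            if bit:
                names.append(f"{self.bands[i // 10]}:{GEO_FEATURE_NAMES[i % 10]}")
        return names


def decode_mask(position: Sequence[float], bands: Sequence[str]) -> FeatureMask:
    """Threshold a real-valued particle at 0 into a feature mask.

    The selection rule is strict: a coordinate of exactly 0 leaves its
    bit unset.
    """
    pos = np.asarray(position, dtype=float)
    return FeatureMask(bits=tuple(int(v) for v in (pos > 0.0)), bands=tuple(bands))


@dataclass(frozen=True)
class NBModel:
    """Gaussian naive Bayes: per-class priors and per-feature moments."""

    classes: tuple
    log_priors: np.ndarray  # (n_classes,)
    means: np.ndarray  # (n_classes, n_features)
    variances: np.ndarray  # (n_classes, n_features), floored at epsilon


def nb_fit(X: np.ndarray, y: Sequence, var_smoothing: float = 1e-9) -> NBModel:
    """Fit Gaussian class-conditionals with variance smoothing.

    Variances are floored at ``var_smoothing`` times the largest
    per-feature variance of the pooled data, so degenerate (constant)
    features keep a finite log-likelihood.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("nb_fit requires at least two classes")
    eps = var_smoothing * float(np.max(X.var(axis=0), initial=0.0))
    if eps <= 0.0:
        eps = var_smoothing
    means, variances, log_priors = [], [], []
    for c in classes:
        rows = X[y == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means.append(rows.mean(axis=0))
        variances.append(np.maximum(rows.var(axis=0), eps))
        log_priors.append(np.log(rows.shape[0] / X.shape[0]))
    return NBModel(
        classes=classes,
        log_priors=np.array(log_priors),
        means=np.array(means),
        variances=np.array(variances),
    )


def nb_predict(model: NBModel, X: np.ndarray) -> np.ndarray:
    """Maximum-posterior class labels for the rows of ``X``.

    Ties go to the first class in sorted label order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    # (samples, classes): log prior + sum of log normal densities
    ll = model.log_priors - 0.5 * np.sum(
        np.log(2.0 * np.pi * model.variances)
        + (X[:, None, :] - model.means[None]) ** 2 / model.variances[None],
        axis=2,
    )
    # argmax takes the first maximum, i.e. the first class in sorted order
    idx = np.argmax(ll, axis=1)
    return np.array([model.classes[i] for i in idx])


def stratified_folds(X: np.ndarray, y: Sequence, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment, invariant to row order.

    Within each class the samples are put into a canonical order
    (lexicographic by their full feature vector), shuffled once with the
    seeded generator, and dealt round-robin into folds.  The assignment
    therefore depends only on the sample *values*, the seed and the
    strata -- not on how the rows happen to be ordered, and not on which
    columns a mask later selects.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = np.empty(len(y), dtype=int)
    rng = np.random.default_rng(seed)
    for c in sorted(set(y.tolist())):
        idx = np.flatnonzero(y == c)
        canonical = idx[np.lexsort(X[idx].T[::-1])]
        shuffled = canonical[rng.permutation(len(canonical))]
        folds[shuffled] = np.arange(len(shuffled)) % n_folds
    return folds


def feature_matrix(
    table: pd.DataFrame, bands: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate the per-band feature blocks of a feature table.

    ``table`` holds one row per (segment, band) as produced by
    :func:`~sodpeeg.sodp_features.extract_features`; the result has one
    row per segment with ``10 x len(bands)`` columns in canonical order,
    plus the label vector.
    """
    blocks = []
    labels = None
    for band in bands:
        sub = table[table.band == band].sort_values("segment_id")
        if sub.empty:
            raise KeyError(f"feature table holds no rows for band {band!r}")
        blocks.append(sub[list(GEO_FEATURE_NAMES)].to_numpy())
        lab = sub["label"].to_numpy()
        if labels is None:
            labels = lab
            ids = sub["segment_id"].to_numpy()
        else:
            if not np.array_equal(ids, sub["segment_id"].to_numpy()):
                raise ValueError("bands cover different segment sets")
    return np.hstack(blocks), labels


def cv_fitness(
    X: np.ndarray,
    y: np.ndarray,
    mask: FeatureMask,
    n_folds: int = 10,
    seed: int = 0,
    fold_ids: np.ndarray | None = None,
) -> float:
    """Mean stratified k-fold naive-Bayes accuracy of the masked features.

    An empty mask scores 0 (the search space stays total).  Precomputed
    ``fold_ids`` may be passed to amortize the assignment across calls;
    they are recomputed deterministically otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    if counts.min() < n_folds:
        raise ValueError(f"need at least {n_folds} samples per class")
    bits = np.asarray(mask.bits, dtype=bool)
    if bits.size != X.shape[1]:
        raise ValueError("mask length does not match the feature matrix")
    if not bits.any():
        return 0.0
    if fold_ids is None:
        fold_ids = stratified_folds(X, y, n_folds, seed)
    Xm = X[:, bits]
    correct = 0
    for k in range(n_folds):
        test = fold_ids == k
        model = nb_fit(Xm[~test], y[~test])
        correct += int(np.sum(nb_predict(model, Xm[test]) == y[test]))
    return correct / len(y)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a multi-trial feature-selection experiment."""

    bands: tuple[str, ...]
    mode: str
    best_mask: FeatureMask
    best_accuracy: float
    trial_accuracies: np.ndarray  # (trials,)
    trial_masks: tuple[FeatureMask, ...]
    trajectories: tuple[Trajectory, ...]

    @property
    def min(self) -> float:
        return float(self.trial_accuracies.min())

    @property
    def max(self) -> float:
        return float(self.trial_accuracies.max())

    @property
    def mean(self) -> float:
        return float(self.trial_accuracies.mean())

    @property
    def mean_dimension(self) -> float:
        """Mean number of selected features over trials."""
        return float(np.mean([m.n_selected for m in self.trial_masks]))


def _make_selection_config(bands: Sequence[str], config: SwarmConfig | None, **overrides):
    dim = 10 * len(bands)
    if config is None:
        config = SwarmConfig(dim=dim, bounds=(-1.0, 1.0), direction="maximize", **overrides)
    else:
        config = replace(config, dim=dim, direction="maximize", **overrides)
    return config


def select_features(
    table: pd.DataFrame,
    bands: Sequence[str],
    config: SwarmConfig | None = None,
    n_folds: int = 10,
    cv_seed: int | None = None,
    **config_overrides,
) -> SelectionResult:
    """Search for the best feature subset over a band combination.

    Runs ``config.trials`` independent seeded optimizations (mode per
    ``config``, default AsyLnCPSO-GA) over particles of length
    ``10 x len(bands)``, each maximizing the cross-validated naive-Bayes
    accuracy of the decoded mask, and aggregates the per-trial bests.

    The fold split is computed once from ``cv_seed`` (default:
    ``config.seed``) and shared by every fitness call, so fitness values
    are comparable across trials and modes, and memoized per mask.
    """
    bands = tuple(bands)
    if bands not in BAND_COMBINATIONS:
        raise ValueError(f"unknown band combination {bands!r}")
    config = _make_selection_config(bands, config, **config_overrides)
    X, y = feature_matrix(table, bands)
    fold_ids = stratified_folds(X, y, n_folds, cv_seed if cv_seed is not None else config.seed)

    cache: dict[tuple[int, ...], float] = {}

    def fitness(position: np.ndarray) -> float:
        mask = decode_mask(position, bands)
        if mask.bits not in cache:
            cache[mask.bits] = cv_fitness(X, y, mask, n_folds=n_folds, fold_ids=fold_ids)
        return cache[mask.bits]

    children = np.random.SeedSequence(config.seed).spawn(config.trials)
    trajectories = [optimize(fitness, config, seed=child) for child in children]
    masks = tuple(decode_mask(t.gbest_position, bands) for t in trajectories)
    accs = np.array([t.final_fitness for t in trajectories])
    best = int(np.argmax(accs))
    return SelectionResult(
        bands=bands,
        mode=config.mode,
        best_mask=masks[best],
        best_accuracy=float(accs[best]),
        trial_accuracies=accs,
        trial_masks=masks,
        trajectories=tuple(trajectories),
    )


def band_cross_experiment(
    table: pd.DataFrame,
    config: SwarmConfig | None = None,
    combinations: Sequence[tuple[str, ...]] = BAND_COMBINATIONS,
    **kwargs,
) -> dict[tuple[str, ...], SelectionResult]:
    """Run :func:`select_features` for every band combination.

    The feature table must hold rows for every band appearing in
    ``combinations``; results come back keyed by combination, from which
    min/max/mean accuracy tables and occurrence statistics are derived.
    """
    results = {}
    for combo in combinations:
        results[combo] = select_features(table, combo, config=config, **kwargs)
    return results
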