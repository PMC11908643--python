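"""Holdout-rate (BestH) selection by inner-split grid search.

The holdout rate H controls how much of the training set feeds the
meta-learner.  BestH is found by splitting the training set once into
an inner training portion (80%, "Train_Blending") and an inner
evaluation portion (20%, "training_test"), fitting a blending ensemble
at each grid value of H on the inner training portion, and scoring
Pearson accuracy on the inner evaluation portion.  The H with the
highest inner accuracy is BestH (ties break to the smallest H); the
final ensemble is refit on the full training set at BestH.

The default grid is H = 0.10, 0.15, ..., 0.60 (11 values), and the same
stratification strategy is used inside tuning as in the final fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import GenotypeMatrix, PhenotypeVector, outer_split
from .ensemble import BlendConfig, fit_blending
from .exceptions import ConstantInputError, TuningError
from .stratify import StratifyConfig

__all__ = ["TuneResult", "DEFAULT_GRID", "optimize_h", "fit_with_besth",
           "select_best_h"]

#: default holdout-rate grid: 0.10 to 0.60 in steps of 0.05
DEFAULT_GRID = tuple(np.round(np.arange(0.10, 0.601, 0.05), 2))


@dataclass
class TuneResult:
    """The (H, inner accuracy) grid and the selected BestH."""

    grid: list  # list of (H, accuracy) pairs, H strictly increasing
    best_h: float
    inner_seed: int

    def __post_init__(self):
        hs = [h for h, _ in self.grid]
        if any(b <= a for a, b in zip(hs, hs[1:])):
            raise ValueError("grid H values must be strictly increasing")
        if self.best_h not in hs:
            raise ValueError("best_h must be a grid value")


def select_best_h(pairs) -> float:
    """Argmax of inner accuracy; ties break to the smallest H.

    Raises :class:`TuningError` if no grid value produced a defined
    accuracy.
    """
    finite = [(h, a) for h, a in pairs if np.isfinite(a)]
    if not finite:
        raise TuningError("no holdout rate produced a defined inner accuracy")
    best_acc = max(a for _, a in finite)
    return min(h for h, a in finite if a == best_acc)


def optimize_h(G: GenotypeMatrix, y: PhenotypeVector, train_idx,
               strategy: str = "random", k: int = 8, grid=None, seed: int = 0,
               inner_fraction: float = 0.2,
               base_learner_settings=None) -> TuneResult:
    """Grid-search the holdout rate on an inner split of the training set.

    The inner split is drawn once (seed-fixed); every H is fitted on the
    same inner training rows and scored on the same inner evaluation
    rows, so the grid values are directly comparable.  An H whose
    predictions are constant (undefined Pearson accuracy) scores -inf
    with a warning.
    """
    from .evalbench import pearson_accuracy  # local import avoids a cycle

    train_idx = np.asarray(train_idx, dtype=int)
    grid = sorted(DEFAULT_GRID) if grid is None else sorted(float(h) for h in grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    if any(not 0.0 < h < 1.0 for h in grid):
        raise ValueError("all grid rates must lie in (0, 1)")

    inner = outer_split(train_idx.size, test_fraction=inner_fraction, seed=seed)
    train_blending = train_idx[inner.train_idx]
    training_test = train_idx[inner.test_idx]
    obs = y.values[training_test]

    pairs = []
    for h in grid:
        cfg = BlendConfig(h=h, stratify=StratifyConfig(strategy=strategy, k=k, seed=seed),
                          base_learner_settings=base_learner_settings or {}, seed=seed)
        ens = fit_blending(G, y, train_blending, cfg)
        pred = ens.predict(G.dosages[training_test])
        try:
            acc = pearson_accuracy(pred, obs).r
        except ConstantInputError:
            warnings.warn(f"H={h}: constant predictions, accuracy undefined",
                          stacklevel=2)
            acc = float("-inf")
        pairs.append((h, acc))
    return TuneResult(grid=pairs, best_h=select_best_h(pairs), inner_seed=seed)


def fit_with_besth(G: GenotypeMatrix, y: PhenotypeVector, train_idx,
                   strategy: str = "random", k: int = 8, grid=None,
                   seed: int = 0, base_learner_settings=None):
    """Tune BestH, then refit on the full training set at that rate."""
    tune = optimize_h(G, y, train_idx, strategy=strategy, k=k, grid=grid,
                      seed=seed, base_learner_settings=base_learner_settings)
    cfg = BlendConfig(h=tune.best_h,
                      stratify=StratifyConfig(strategy=strategy, k=k, seed=seed),
                      base_learner_settings=base_learner_settings or {}, seed=seed)
    ensemble = fit_blending(G, y, np.asarray(train_idx, dtype=int), cfg)
    return ensemble, tune
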