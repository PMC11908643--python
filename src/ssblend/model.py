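"""Model/Results surface over the blending machinery.

``SSBlending`` bundles aligned genotypes and one phenotype with a
strategy choice; ``fit()`` performs the outer train/test split, tunes
the holdout rate on the training set (unless a fixed rate is given),
refits at BestH, and returns an :class:`SSBlendingResults` carrying the
fitted ensemble, the tuning trace, test-set accuracy and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dataio
from .dataio import DataSplit, GenotypeMatrix, PhenotypeVector, align, outer_split
from .ensemble import BlendConfig, BlendEnsemble, fit_blending
from .evalbench import pearson_accuracy, sample_skewness
from .stratify import StratifyConfig
from .tuning import DEFAULT_GRID, TuneResult, optimize_h

__all__ = ["SSBlending", "SSBlendingResults"]


class SSBlending:
    """A stratified-sampling blending model for one quantitative trait.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    phenotype : PhenotypeVector
        Aligned to the genotypes on construction (shared sample IDs).
    strategy : {"random", "ca", "pp"}
        How the meta-training holdout is drawn; ``"random"`` is
        conventional blending.
    k : int
        Number of strata (layers) for the CA/PP strategies.
    test_fraction : float
        Fraction of samples held out as the outer test set.
    seed : int
        Master seed for the outer split, holdout draws and learners.
    """

    def __init__(self, genotypes: GenotypeMatrix, phenotype: PhenotypeVector,
                 strategy: str = "random", k: int = 8,
                 test_fraction: float = 0.2, seed: int = 0,
                 base_learner_settings: dict | None = None):
        self.genotypes, self.phenotype = align(genotypes, phenotype)
        self.strategy = strategy
        self.k = k
        self.test_fraction = test_fraction
        self.seed = seed
        self.base_learner_settings = base_learner_settings or {}
        self.split: DataSplit = outer_split(self.genotypes.n_samples,
                                            test_fraction=test_fraction, seed=seed)

    @classmethod
    def from_dataframe(cls, genotypes: pd.DataFrame, phenotype: pd.Series,
                       **kwargs) -> "SSBlending":
        """Build from a dosage DataFrame (index = sample IDs) and a trait Series."""
        G = GenotypeMatrix(sample_ids=[str(s) for s in genotypes.index],
                           marker_ids=[str(c) for c in genotypes.columns],
                           dosages=genotypes.to_numpy(dtype=float))
        y = PhenotypeVector(sample_ids=[str(s) for s in phenotype.index],
                            values=phenotype.to_numpy(dtype=float),
                            trait_name=str(phenotype.name or "trait"))
        return cls(G, y, **kwargs)

    @classmethod
    def from_files(cls, genotype_path, phenotype_path, trait: str,
                   genotype_format: str = "csv", **kwargs) -> "SSBlending":
        G = dataio.read_genotypes(genotype_path, format=genotype_format)
        y = dataio.read_phenotypes(phenotype_path, trait=trait)
        return cls(G, y, **kwargs)

    def fit(self, holdout_rate: float | None = None, grid=None) -> "SSBlendingResults":
        """Fit the ensemble; tune BestH unless a fixed rate is given."""
        G, y = self.genotypes, self.phenotype
        tune = None
        if holdout_rate is None:
            grid = list(DEFAULT_GRID) if grid is None else list(grid)
            tune = optimize_h(G, y, self.split.train_idx, strategy=self.strategy,
                              k=self.k, grid=grid, seed=self.seed,
                              base_learner_settings=self.base_learner_settings)
            holdout_rate = tune.best_h
        cfg = BlendConfig(h=holdout_rate,
                          stratify=StratifyConfig(strategy=self.strategy, k=self.k,
                                                  seed=self.seed),
                          base_learner_settings=self.base_learner_settings,
                          seed=self.seed)
        ensemble = fit_blending(G, y, self.split.train_idx, cfg)
        return SSBlendingResults(model=self, ensemble=ensemble, tune=tune)


@dataclass
class SSBlendingResults:
    """Results of one fitted (optionally tuned) blending ensemble."""

    model: SSBlending
    ensemble: BlendEnsemble
    tune: TuneResult | None = None

    def __post_init__(self):
        G, y, split = self.model.genotypes, self.model.phenotype, self.model.split
        self.test_predictions = self.ensemble.predict(G.dosages[split.test_idx])
        self.test_observed = y.values[split.test_idx]
        try:
            self.accuracy = pearson_accuracy(self.test_predictions,
                                             self.test_observed).r
        except Exception:
            self.accuracy = float("nan")

    @property
    def params(self) -> pd.Series:
        """Meta-model coefficients (intercept + one weight per base learner)."""
        meta = self.ensemble.meta
        return pd.Series([meta.intercept, *meta.coefficients],
                         index=["intercept", "svr", "tree", "enet"])

    @property
    def best_h(self) -> float:
        return self.ensemble.config.h

    def predict(self, G_new) -> np.ndarray:
        return self.ensemble.predict(G_new)

    def summary(self) -> str:
        m = self.model
        lines = [
            "            Stratified-Sampling Blending Results",
            "=" * 60,
            f"Trait:               {m.phenotype.trait_name}",
            f"Samples (train/test): {m.split.train_idx.size} / {m.split.test_idx.size}",
            f"Markers:             {m.genotypes.n_markers}",
            f"Strategy:            {m.strategy} (K={m.k})",
            f"Holdout rate H:      {self.best_h:.2f}"
            + ("  (BestH, tuned)" if self.tune is not None else "  (fixed)"),
            f"Trait skewness:      {sample_skewness(m.phenotype.values):.4f}",
            f"Test Pearson r:      {self.accuracy:.4f}",
            "-" * 60,
            "Meta-model (OLS on base-learner predictions):",
        ]
        for name, val in self.params.items():
            lines.append(f"    {name:<10} {val: .6f}")
        if self.tune is not None:
            lines.append("-" * 60)
            lines.append("BestH grid (H : inner accuracy):")
            for h, acc in self.tune.grid:
                flag = "  <- BestH" if h == self.tune.best_h else ""
                lines.append(f"    {h:.2f} : {acc: .4f}{flag}")
        lines.append("=" * 60)
        return "\n".join(lines)
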