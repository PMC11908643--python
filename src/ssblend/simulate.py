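"""Synthetic genotype/phenotype simulation for quantitative traits.

The generator implements the standard additive model

    y = X beta + e

where X is an n x m allele-dosage matrix, a random subset of q markers
(the QTNs, quantitative trait nucleotides) carries effects beta drawn
from a standard normal, g = X[:, qtn] beta is the genetic value, and the
residual e is Gaussian with variance calibrated so that the narrow-sense
heritability h2 = var(g)/var(y) hits its target in expectation:

    sigma2_e = var(g) * (1 - h2) / h2.

Genotypes are simulated as independent binomial dosages: each marker j
gets an allele frequency p_j ~ Uniform(maf_low, maf_high) and each
individual's dosage is Binomial(2, p_j).  This deliberately omits
linkage disequilibrium and population structure — the simulator exists
to exercise prediction and stratification machinery under a known
genetic architecture, not to mimic a specific genome.

The study grid crosses h2 in {0.2, 0.5, 0.8} with QTN counts in
{200, 2000, 5000} (nine architectures); ``simulate_grid`` reproduces it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import product

import numpy as np

from .dataio import GenotypeMatrix, PhenotypeVector
from .exceptions import SimulationError

__all__ = [
    "SimParams",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_dataset",
    "simulate_grid",
    "GRID_H2",
    "GRID_QTN",
]

#: heritability levels of the simulation grid
GRID_H2 = (0.2, 0.5, 0.8)
#: QTN counts of the simulation grid
GRID_QTN = (200, 2000, 5000)


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated dataset.

    n, m : sample and marker counts.
    n_qtn : number of causal markers (q <= m).
    h2 : target narrow-sense heritability in (0, 1].
    maf_low, maf_high : bounds of the uniform allele-frequency draw,
        in (0, 0.5].
    seed : master seed; genotype and phenotype streams are derived
        from it independently.
    """

    n: int = 3000
    m: int = 20000
    n_qtn: int = 200
    h2: float = 0.5
    maf_low: float = 0.05
    maf_high: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.m < 1:
            raise ValueError(f"need n >= 2, m >= 1; got n={self.n}, m={self.m}")
        if not 1 <= self.n_qtn <= self.m:
            raise ValueError(f"n_qtn must be in [1, m={self.m}], got {self.n_qtn}")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError(
                f"need 0 < maf_low <= maf_high <= 0.5, got "
                f"({self.maf_low}, {self.maf_high})"
            )


@dataclass
class SimulatedDataset:
    """A simulated dataset together with its generating truth."""

    G: GenotypeMatrix
    y: PhenotypeVector
    qtn_idx: np.ndarray
    beta: np.ndarray
    g: np.ndarray  #: genetic values X[:, qtn] @ beta
    e: np.ndarray  #: residuals
    realized_h2: float
    params: SimParams
    label: str = ""


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_genotypes(params: SimParams) -> GenotypeMatrix:
    """Draw independent binomial dosages with uniform allele frequencies."""
    rng = _rng(params.seed, 0)
    p = rng.uniform(params.maf_low, params.maf_high, size=params.m)
    # Binomial(2, p) drawn as the sum of two Bernoulli fields (one per
    # haplotype) — equivalent in law and much faster than rng.binomial
    # for large n x m
    dosages = (rng.random((params.n, params.m)) < p).astype(np.float64)
    dosages += rng.random((params.n, params.m)) < p
    sample_ids = [f"S{i + 1:05d}" for i in range(params.n)]
    marker_ids = [f"M{j + 1:06d}" for j in range(params.m)]
    return GenotypeMatrix(sample_ids=sample_ids, marker_ids=marker_ids, dosages=dosages)


def simulate_phenotype(G: GenotypeMatrix, params: SimParams) -> SimulatedDataset:
    """Simulate y = X beta + e on an existing genotype matrix.

    QTNs are sampled without replacement, effects are standard normal,
    and the residual variance is calibrated to the realized sample
    variance of the genetic values so that var(g)/var(y) concentrates on
    the target h2.  If every sampled QTN is monomorphic (var(g) = 0) the
    QTN set is resampled up to 10 times before failing.
    """
    if params.n_qtn > G.n_markers:
        raise ValueError(
            f"n_qtn={params.n_qtn} exceeds marker count {G.n_markers}"
        )
    rng = _rng(params.seed, 1)
    q = params.n_qtn
    for _ in range(10):
        qtn_idx = np.sort(rng.choice(G.n_markers, size=q, replace=False))
        beta = rng.standard_normal(q)
        g = G.dosages[:, qtn_idx] @ beta
        var_g = float(np.var(g, ddof=1))
        if var_g > 0.0:
            break
    else:
        raise SimulationError(
            "all sampled QTN sets were monomorphic after 10 attempts; "
            "increase marker polymorphism or n_qtn"
        )
    if params.h2 >= 1.0:
        e = np.zeros_like(g)
    else:
        sigma2_e = var_g * (1.0 - params.h2) / params.h2
        e = rng.normal(0.0, np.sqrt(sigma2_e), size=G.n_samples)
    y_vals = g + e
    realized_h2 = var_g / float(np.var(y_vals, ddof=1))
    y = PhenotypeVector(sample_ids=list(G.sample_ids), values=y_vals,
                        trait_name="simulated")
    return SimulatedDataset(G=G, y=y, qtn_idx=qtn_idx, beta=beta, g=g, e=e,
                            realized_h2=realized_h2, params=params)


def simulate_dataset(params: SimParams) -> SimulatedDataset:
    """Genotypes plus phenotype in one call."""
    return simulate_phenotype(simulate_genotypes(params), params)


def _child_seed(base_seed: int, index: int) -> int:
    state = np.random.SeedSequence([int(base_seed), 1000 + index]).generate_state(1)[0]
    return int(state % (2**31))


def simulate_grid(base: SimParams) -> dict:
    """Cross h2 in {0.2, 0.5, 0.8} with q in {200, 2000, 5000}.

    Returns a dict mapping labels like ``"h0.2_q200"`` to datasets.  QTN
    counts exceeding the marker count are capped at m (with a warning)
    and duplicate architectures are dropped, so the grid still runs at
    reduced scale.
    """
    datasets = {}
    idx = 0
    for h2, q in product(GRID_H2, GRID_QTN):
        if q > base.m:
            warnings.warn(
                f"QTN count {q} exceeds marker count m={base.m}; capping at {base.m}",
                stacklevel=2,
            )
            q = base.m
        label = f"h{h2}_q{q}"
        if label in datasets:
            continue
        params = replace(base, h2=h2, n_qtn=q, seed=_child_seed(base.seed, idx))
        ds = simulate_dataset(params)
        ds.label = label
        datasets[label] = ds
        idx += 1
    return datasets
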