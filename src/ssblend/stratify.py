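"""Stratification strategies and stratified holdout sampling.

Two ways of splitting a population into K strata ("layers") before
drawing the blending holdout set:

* **CA (cluster analysis)** — k-means clustering of the genotype
  dosage matrix; strata are clusters, sampling weights proportional to
  cluster size (proportional allocation preserves the population's
  composition in the holdout).

* **PP (phenotype probability)** — the phenotype range is cut into K
  equal-width intervals; a Gaussian kernel density estimate of the trait
  is integrated over each interval with a midpoint Riemann rule, and the
  (renormalized) interval probabilities become the sampling weights.

Given an assignment, ``stratified_sample`` draws a holdout of exactly
``round(H * n)`` individuals: per-stratum quotas come from
largest-remainder (Hamilton) apportionment of the target by the weights,
with quotas exceeding a stratum's occupancy capped and the overflow
redistributed to the remaining strata.  ``random_sample`` is the simple
random draw used by conventional blending; with K = 1 the stratified
draw reduces to it exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans

from .dataio import GenotypeMatrix, PhenotypeVector
from .exceptions import DegeneratePhenotypeError, SizeError

__all__ = [
    "StratifyConfig",
    "StrataAssignment",
    "stratify_ca",
    "stratify_pp",
    "stratified_sample",
    "random_sample",
    "largest_remainder",
]


@dataclass(frozen=True)
class StratifyConfig:
    """How to stratify before holdout sampling.

    strategy : one of ``"random"``, ``"ca"``, ``"pp"``.
    k : number of strata (layers); the study default is 8.
    seed : controls k-means initialization.
    pp_grid_points : abscissae of the midpoint Riemann rule (>= 100).
    pp_bandwidth_rule : KDE bandwidth selector (``"silverman"`` or
        ``"scott"``).
    pp_empirical_counts : weight intervals by their empirical member
        counts instead of the integrated density mass.
    ca_top_variance_markers : if set, run k-means on only the most
        variable markers (a cheap stand-in for upstream dimensionality
        reduction on very wide matrices).
    """

    strategy: str = "random"
    k: int = 8
    seed: int = 0
    pp_grid_points: int = 1000
    pp_bandwidth_rule: str = "silverman"
    pp_empirical_counts: bool = False
    ca_top_variance_markers: int | None = None

    def __post_init__(self):
        if self.strategy not in ("random", "ca", "pp"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.pp_grid_points < 100:
            raise ValueError(f"pp_grid_points must be >= 100, got {self.pp_grid_points}")


@dataclass
class StrataAssignment:
    """Per-individual stratum labels (1..K) with sampling weights.

    Every represented stratum is non-empty: empty strata are dropped at
    construction time and labels/weights are compacted.
    """

    labels: np.ndarray
    weights: np.ndarray
    occupied: np.ndarray = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        k = self.weights.size
        if self.labels.min() < 1 or self.labels.max() > k:
            raise ValueError("labels must lie in 1..K")
        counts = np.bincount(self.labels, minlength=k + 1)[1:]
        if (counts == 0).any():
            # compact away empty strata and renormalize
            keep = counts > 0
            remap = np.cumsum(keep)
            self.labels = remap[self.labels - 1]
            self.weights = self.weights[keep]
            counts = counts[keep]
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("stratum weights must have positive sum")
        self.weights = self.weights / total
        self.occupied = counts

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def k(self) -> int:
        return self.weights.size

    def members(self, stratum: int) -> np.ndarray:
        return np.flatnonzero(self.labels == stratum)


def stratify_ca(G: GenotypeMatrix, config: StratifyConfig) -> StrataAssignment:
    """Cluster-analysis stratification: k-means on the dosage matrix.

    Weights are proportional to cluster sizes.  If k-means leaves a
    cluster empty the stratum count is reduced with a warning.
    """
    n = G.n_samples
    if config.k > n:
        raise SizeError(f"k={config.k} strata exceed n={n} individuals")
    X = G.dosages
    if config.ca_top_variance_markers is not None and config.ca_top_variance_markers < G.n_markers:
        var = X.var(axis=0)
        top = np.sort(np.argsort(var)[::-1][: config.ca_top_variance_markers])
        X = X[:, top]
    km = KMeans(n_clusters=config.k, n_init=10, random_state=config.seed)
    raw = km.fit_predict(X)
    counts = np.bincount(raw, minlength=config.k).astype(float)
    if (counts == 0).any():
        warnings.warn(
            f"k-means left {int((counts == 0).sum())} empty cluster(s); "
            f"reducing stratum count",
            stacklevel=2,
        )
    # proportional allocation: weight = cluster size; StrataAssignment
    # drops zero-weight (empty) strata and renormalizes
    return StrataAssignment(labels=raw + 1, weights=counts)


def stratify_pp(y: PhenotypeVector, config: StratifyConfig) -> StrataAssignment:
    """Phenotype-probability stratification.

    [min(y), max(y)] is split into K equal-width intervals (the last
    right-closed).  A Gaussian KDE of the trait is integrated over each
    interval by the midpoint Riemann rule on ``pp_grid_points``
    abscissae; the renormalized interval masses are the sampling
    weights.  Empty intervals are dropped (weights renormalized over the
    occupied ones).
    """
    v = np.asarray(y.values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise DegeneratePhenotypeError("phenotype is constant; cannot stratify by density")
    k = config.k
    edges = np.linspace(lo, hi, k + 1)
    # interior edges: [e0,e1), ..., [e_{K-1}, e_K]; max lands in the last bin
    labels = np.digitize(v, edges[1:-1], right=False) + 1

    if config.pp_empirical_counts:
        weights = np.bincount(labels, minlength=k + 1)[1:].astype(float)
    else:
        kde = gaussian_kde(v, bw_method=config.pp_bandwidth_rule)
        npts = config.pp_grid_points
        dx = (hi - lo) / npts
        mids = lo + dx * (np.arange(npts) + 0.5)
        dens = kde(mids)
        mid_bins = np.digitize(mids, edges[1:-1], right=False)
        masses = np.bincount(mid_bins, weights=dens * dx, minlength=k)
        weights = masses / masses.sum()
        # zero weight for unoccupied intervals so they are dropped
        counts = np.bincount(labels, minlength=k + 1)[1:]
        weights = np.where(counts > 0, weights, 0.0)
        if weights.sum() <= 0:
            weights = counts.astype(float)
    return StrataAssignment(labels=labels, weights=weights)


def largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Hamilton apportionment of ``total`` units by ``weights``.

    Floors of the ideal shares are assigned first, then the leftover
    units go to the largest fractional remainders; ties break toward the
    lower index.  The result always sums to ``total`` exactly.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    share = weights / weights.sum() * total
    base = np.floor(share).astype(int)
    leftover = total - int(base.sum())
    if leftover > 0:
        frac = share - base
        # stable sort on -frac => ties resolved by lower index
        order = np.argsort(-frac, kind="stable")
        base[order[:leftover]] += 1
    return base


def _capped_quotas(total: int, weights: np.ndarray, occupied: np.ndarray) -> np.ndarray:
    """Largest-remainder quotas capped at occupancy, overflow redistributed."""
    k = weights.size
    quotas = np.zeros(k, dtype=int)
    remaining = int(total)
    active = occupied > 0
    while remaining > 0:
        w = np.where(active, weights, 0.0)
        if w.sum() <= 0:
            # residual weights exhausted but capacity remains: spread by capacity
            w = np.where(active, (occupied - quotas).astype(float), 0.0)
        alloc = np.zeros(k, dtype=int)
        alloc[active] = largest_remainder(remaining, w[active])
        give = np.minimum(alloc, occupied - quotas)
        quotas += give
        remaining -= int(give.sum())
        active = quotas < occupied
        if not active.any():
            break
    if remaining > 0:
        raise SizeError(f"target {total} exceeds population size {occupied.sum()}")
    return quotas


def stratified_sample(assignment: StrataAssignment, H: float, seed: int = 0) -> np.ndarray:
    """Draw a stratified holdout of exactly ``round(H * n)`` individuals.

    Per-stratum quotas are the largest-remainder apportionment of the
    target by the assignment weights, capped at each stratum's occupancy
    with overflow redistributed by residual weight; within a stratum,
    members are drawn uniformly without replacement.
    """
    n = assignment.n
    T = _target_size(n, H)
    quotas = _capped_quotas(T, assignment.weights, assignment.occupied)
    rng = np.random.default_rng(seed)
    picks = []
    for s in range(1, assignment.k + 1):
        members = assignment.members(s)
        q = quotas[s - 1]
        if q > 0:
            picks.append(rng.choice(members, size=q, replace=False))
    out = np.sort(np.concatenate(picks)) if picks else np.empty(0, dtype=int)
    assert out.size == T
    return out


def random_sample(n: int, H: float, seed: int = 0) -> np.ndarray:
    """Simple random holdout of size ``round(H * n)`` (conventional blending)."""
    T = _target_size(n, H)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(np.arange(n), size=T, replace=False))


def _target_size(n: int, H: float) -> int:
    if not 0.0 < H < 1.0:
        raise ValueError(f"holdout rate H must be in (0, 1), got {H}")
    T = int(round(H * n))
    if T < 1:
        raise SizeError(f"holdout rate H={H} yields an empty holdout for n={n}")
    if T > n:
        raise SizeError(f"holdout size {T} exceeds n={n}")
    return T
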