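"""Genotype/phenotype I/O, sample alignment and outer train/test splitting.

Genotypes are SNP allele dosages (0/1/2 copies of the counted allele per
diploid individual), read either from a plain CSV (header row of marker
IDs, first column the sample ID) or from a PLINK ``.raw`` additive-dosage
file as written by ``plink --recode A``.  Missing dosages (``NA`` or the
PLINK missing code ``-9``) are imputed with the per-marker mean at load
time; markers with zero variance are kept but flagged so downstream
feature filters can drop them.

Phenotypes come from a TSV whose first column is the sample ID with one
or more named numeric trait columns; individuals missing the requested
trait are dropped, mirroring standard genomic-evaluation practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, FormatError, SizeError

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "DataSplit",
    "read_genotypes",
    "read_phenotypes",
    "align",
    "outer_split",
    "write_genotypes",
    "write_phenotypes",
    "write_predictions",
]

#: tokens treated as a missing dosage on input
_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", "-9", "-9.0"}

_PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class GenotypeMatrix:
    """An n-samples x m-markers allele-dosage matrix.

    Attributes
    ----------
    sample_ids : list of str
        Row identifiers, in matrix row order.
    marker_ids : list of str
        Column identifiers, in matrix column order.
    dosages : ndarray of float, shape (n, m)
        Allele dosages, nominally in [0, 2]; no missing values remain
        after load-time imputation.
    monomorphic : ndarray of bool, shape (m,)
        Markers whose dosage is constant across all samples (flagged at
        load; retained in the matrix).
    """

    sample_ids: list
    marker_ids: list
    dosages: np.ndarray
    monomorphic: np.ndarray = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        n, m = self.dosages.shape
        if n < 2 or m < 1:
            raise SizeError(f"need at least 2 samples and 1 marker, got {n} x {m}")
        if len(self.sample_ids) != n or len(self.marker_ids) != m:
            raise ValueError("ID lengths do not match dosage shape")
        if np.isnan(self.dosages).any():
            raise ValueError("dosages contain missing values after load")
        if self.monomorphic is None:
            self.monomorphic = self.dosages.std(axis=0) == 0.0
        self.monomorphic = np.asarray(self.monomorphic, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def take(self, idx) -> "GenotypeMatrix":
        """Row-subset by positional indices, preserving order of ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            dosages=self.dosages[idx],
            monomorphic=self.monomorphic,
        )


@dataclass
class PhenotypeVector:
    """A named quantitative trait over an ordered set of samples."""

    sample_ids: list
    values: np.ndarray
    trait_name: str = "trait"
    n_dropped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("phenotype values must be 1-D")
        if len(self.sample_ids) != self.values.size:
            raise ValueError("sample_ids and values lengths differ")
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype values must be finite")

    def __len__(self) -> int:
        return self.values.size

    def take(self, idx) -> "PhenotypeVector":
        idx = np.asarray(idx, dtype=int)
        return PhenotypeVector(
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[idx],
            trait_name=self.trait_name,
        )


@dataclass
class DataSplit:
    """A disjoint train/test partition of row indices 0..n-1."""

    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if self.train_idx.size == 0 or self.test_idx.size == 0:
            raise SizeError("both train and test must be non-empty")
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")

    @property
    def n(self) -> int:
        return self.train_idx.size + self.test_idx.size


def _parse_dosage_frame(frame: pd.DataFrame, path) -> np.ndarray:
    """Convert a string dosage frame to floats with mean imputation."""
    tokens = frame.astype(str).apply(lambda c: c.str.strip())
    missing = tokens.isin(_MISSING_TOKENS) | frame.isna()
    numeric = tokens.mask(missing.to_numpy()).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy() & ~missing.to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric dosage {tokens.iat[i, j]!r} at row "
            f"{i + 1}, marker column {frame.columns[j]!r}"
        )
    out = numeric.to_numpy(dtype=float)
    miss = missing.to_numpy()
    if miss.any():
        # per-marker mean of observed entries; an all-missing marker -> 0
        with np.errstate(invalid="ignore"):
            col_means = np.nanmean(np.where(miss, np.nan, out), axis=0)
        col_means = np.nan_to_num(col_means, nan=0.0)
        out = np.where(miss, col_means[np.newaxis, :], out)
    return out


def read_genotypes(path, format: str = "csv") -> GenotypeMatrix:
    """Read an allele-dosage matrix from ``csv`` or ``plink_raw`` format.

    Missing entries (``NA``/``-9``) are replaced by the per-marker mean
    dosage.  Zero-variance markers are retained but flagged in
    ``monomorphic``.
    """
    if format == "csv":
        try:
            frame = pd.read_csv(path, index_col=0, dtype=str)
        except Exception as exc:  # pandas reports the offending line
            raise FormatError(f"could not parse genotype CSV {path}: {exc}") from exc
        if frame.shape[1] < 1:
            raise FormatError(f"{path}: no marker columns found after the sample-ID column")
        sample_ids = [str(s) for s in frame.index]
        marker_ids = [str(c) for c in frame.columns]
    elif format == "plink_raw":
        try:
            frame = pd.read_csv(path, sep=r"\s+", dtype=str)
        except Exception as exc:
            raise FormatError(f"could not parse PLINK .raw file {path}: {exc}") from exc
        missing_meta = [c for c in _PLINK_META_COLS if c not in frame.columns]
        if missing_meta:
            raise FormatError(
                f"{path}: not a PLINK .raw dosage file — header lacks "
                f"column(s) {missing_meta} (line 1)"
            )
        sample_ids = [str(s) for s in frame["IID"]]
        marker_cols = [c for c in frame.columns if c not in _PLINK_META_COLS]
        if not marker_cols:
            raise FormatError(f"{path}: no SNP dosage columns after the six metadata columns")
        marker_ids = list(marker_cols)
        frame = frame[marker_cols]
    else:
        raise ValueError(f"unknown genotype format {format!r}; use 'csv' or 'plink_raw'")

    dosages = _parse_dosage_frame(frame, path)
    return GenotypeMatrix(sample_ids=sample_ids, marker_ids=marker_ids, dosages=dosages)


def read_phenotypes(path, trait: str) -> PhenotypeVector:
    """Read one trait from a phenotype TSV (first column = sample ID).

    Individuals with a missing value for the requested trait are
    dropped; the number removed is recorded in ``n_dropped``.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"could not parse phenotype TSV {path}: {exc}") from exc
    if trait not in frame.columns:
        raise KeyError(
            f"trait {trait!r} not found in {path}; available traits: "
            f"{sorted(frame.columns)}"
        )
    col = frame[trait]
    values = []
    ids = []
    n_dropped = 0
    for sid, tok in col.items():
        tok = "" if tok is None or (isinstance(tok, float) and np.isnan(tok)) else str(tok).strip()
        if tok in _MISSING_TOKENS:
            n_dropped += 1
            continue
        try:
            values.append(float(tok))
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric phenotype {tok!r} for sample {sid!r}, trait {trait!r}"
            ) from None
        ids.append(str(sid))
    return PhenotypeVector(sample_ids=ids, values=np.asarray(values), trait_name=trait,
                           n_dropped=n_dropped)


def align(G: GenotypeMatrix, y: PhenotypeVector):
    """Restrict genotypes and phenotype to their shared sample IDs.

    Row order follows the genotype matrix.  Raises
    :class:`AlignmentError` when fewer than two IDs are shared.
    """
    pheno_pos = {sid: i for i, sid in enumerate(y.sample_ids)}
    g_rows, p_rows = [], []
    for i, sid in enumerate(G.sample_ids):
        j = pheno_pos.get(sid)
        if j is not None:
            g_rows.append(i)
            p_rows.append(j)
    if len(g_rows) < 2:
        raise AlignmentError(
            f"genotypes and phenotypes share only {len(g_rows)} sample ID(s); need >= 2"
        )
    return G.take(g_rows), y.take(p_rows)


def outer_split(n: int, test_fraction: float = 0.2, seed: int = 0) -> DataSplit:
    """Uniformly random train/test partition of ``n`` samples.

    ``|test| = round(n * test_fraction)``; deterministic under ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n_test = int(round(n * test_fraction))
    if n < 2 or n_test < 1 or n_test >= n:
        raise SizeError(
            f"cannot split n={n} with test_fraction={test_fraction} "
            f"(test size {n_test})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return DataSplit(train_idx=np.sort(perm[n_test:]), test_idx=np.sort(perm[:n_test]))


def write_genotypes(G: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as CSV (round-trips with read_genotypes)."""
    frame = pd.DataFrame(G.dosages, index=G.sample_ids, columns=G.marker_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path)


def write_phenotypes(y: PhenotypeVector, path) -> None:
    frame = pd.DataFrame({y.trait_name: y.values}, index=y.sample_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def write_predictions(sample_ids, observed, predicted, path) -> None:
    """Write per-sample observed/predicted values as TSV."""
    frame = pd.DataFrame(
        {"observed": np.asarray(observed, float), "predicted": np.asarray(predicted, float)},
        index=list(sample_ids),
    )
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")
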