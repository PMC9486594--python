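"""Genetic similarity matrices.

The default kinship is the realized relationship (genomic relationship)
matrix in VanRaden scaling: with dosage matrix G (n x m) and allele
frequencies p_j computed from the analysis samples,

    W = G - 2p,    K = W W^T / (2 * sum_j p_j (1 - p_j)).

This keeps diag(K) ~ 1 for a sample in Hardy-Weinberg proportions, so the
genetic variance component is on the heritability-friendly scale.  Any
other similarity matrix can be supplied through :func:`read_kinship`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data_io import DataError, GenotypeMatrix

logger = logging.getLogger(__name__)

RIDGE_LADDER = (0.0, 1e-10, 1e-8, 1e-6, 1e-4)


@dataclass
class KinshipMatrix:
    sample_ids: np.ndarray
    values: np.ndarray          # (n, n) symmetric PSD

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise DataError(f"kinship must be {n}x{n}, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("kinship matrix not symmetric")


def realized_relationship(genotype: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden realized relationship matrix from the aligned genotypes."""
    p = genotype.allele_frequencies()
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise DataError("all markers monomorphic; kinship denominator is zero")
    W = genotype.dosages - 2.0 * p
    K = (W @ W.T) / denom
    K = 0.5 * (K + K.T)         # exact symmetry against round-off
    return KinshipMatrix(genotype.sample_ids, K)


def stabilize(kinship: KinshipMatrix) -> KinshipMatrix:
    """Return a kinship whose Cholesky factor exists, adding the smallest
    working diagonal ridge from ``RIDGE_LADDER`` if necessary."""
    if not np.allclose(kinship.values, kinship.values.T, atol=1e-10):
        raise DataError("stabilize requires a symmetric matrix")
    for ridge in RIDGE_LADDER:
        K = kinship.values if ridge == 0.0 else kinship.values + ridge * np.eye(len(kinship.values))
        try:
            np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            continue
        if ridge > 0.0:
            logger.info("stabilize: added ridge %.0e to kinship diagonal", ridge)
            return KinshipMatrix(kinship.sample_ids, K)
        return kinship
    raise DataError("kinship not positive definite for any ridge in the ladder")


def read_kinship(path: str | Path) -> KinshipMatrix:
    """Read a square similarity matrix from CSV (ids in first row/column)
    or HDF5 (datasets ``sample_ids`` and ``kinship``)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ids = f["sample_ids"].asstr()[:]
            K = f["kinship"][:].astype(np.float64)
    else:
        df = pd.read_csv(path, index_col=0)
        ids = df.index.to_numpy(dtype=str)
        K = df.to_numpy(dtype=np.float64)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise DataError(f"kinship in {path} is not square: {K.shape}")
    if K.shape[0] != len(ids):
        raise DataError("kinship id count does not match matrix size")
    asym = np.max(np.abs(K - K.T)) if K.size else 0.0
    if asym > 1e-8:
        raise DataError(f"kinship asymmetric beyond tolerance (max |K-K^T| = {asym:.3g})")
    if asym > 0:
        K = 0.5 * (K + K.T)
    return KinshipMatrix(ids, K)


def write_kinship_csv(kinship: KinshipMatrix, path: str | Path) -> None:
    df = pd.DataFrame(kinship.values, index=kinship.sample_ids, columns=kinship.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.12g")
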