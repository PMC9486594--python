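"""Genotype, phenotype, covariate and result I/O.

Supported genotype formats
--------------------------
CSV    first column sample id, header row of marker ids, one dosage column
       per marker.  Marker ids of the form ``chrom:pos`` (or ``chrom_pos``)
       populate chromosome/position metadata; otherwise markers are placed
       on chromosome "1" at consecutive positions.
HDF5   datasets ``sample_ids``, ``marker_ids``, ``chromosomes``,
       ``positions`` and a chunked ``dosages`` matrix (samples x markers).
       Chunking allows the scan to stream markers without loading the full
       matrix.
PLINK  1.9 binary bed/bim/fam triplet (SNP-major).

Internally a dosage always counts copies of the MINOR allele (0/1/2 for
hard calls, fractional for imputed data); PLINK's A1 counting is flipped
per marker where needed so MAF/MAC filters and effect signs are uniform.
Missing calls are mean-imputed per marker at load time.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_PLINK_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

_MARKER_ID_RE = re.compile(r"^(?P<chrom>[^:_]+)[:_](?P<pos>\d+)$")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GenotypeMatrix:
    """n samples x m markers of minor-allele dosages plus marker metadata."""

    sample_ids: np.ndarray          # (n,) str
    dosages: np.ndarray             # (n, m) float64 in [0, 2]
    marker_ids: np.ndarray          # (m,) str
    chromosomes: np.ndarray         # (m,) str
    positions: np.ndarray           # (m,) int64, 1-based

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.marker_ids = np.asarray(self.marker_ids, dtype=str)
        self.chromosomes = np.asarray(self.chromosomes, dtype=str)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n, m = self.dosages.shape
        if n < 2:
            raise DataError(f"need at least 2 samples, got {n}")
        if m < 1:
            raise DataError("need at least 1 marker")
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample ids in genotype")
        if len(self.marker_ids) != m or len(self.chromosomes) != m or len(self.positions) != m:
            raise DataError("marker metadata length mismatch")
        if np.any(self.positions <= 0):
            raise DataError("positions must be strictly positive (1-based)")
        if np.any(self.dosages < -1e-9) or np.any(self.dosages > 2 + 1e-9):
            raise DataError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the counted (minor) allele."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def mac(self) -> np.ndarray:
        counts = self.dosages.sum(axis=0)
        return np.minimum(counts, 2.0 * self.n_samples - counts)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            dosages=self.dosages[:, index],
            marker_ids=self.marker_ids[index],
            chromosomes=self.chromosomes[index],
            positions=self.positions[index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids[index],
            dosages=self.dosages[index, :],
            marker_ids=self.marker_ids,
            chromosomes=self.chromosomes,
            positions=self.positions,
        )


@dataclass
class PhenotypeVector:
    """Trait values per sample; NaN marks missing on input."""

    sample_ids: np.ndarray
    values: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.sample_ids) != len(self.values):
            raise DataError("phenotype ids/values length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids in phenotype (average replicates first)")


@dataclass
class CovariateMatrix:
    """Real-valued covariates (excluding intercept and marker columns)."""

    sample_ids: np.ndarray
    values: np.ndarray          # (n, k)
    names: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.names = np.asarray(self.names, dtype=str)
        if self.values.shape[0] != len(self.sample_ids):
            raise DataError("covariate ids/rows mismatch")


@dataclass
class AlignedDataset:
    """Genotype, phenotype, optional covariates and kinship on one sample order."""

    genotype: GenotypeMatrix
    phenotype: PhenotypeVector
    kinship: "np.ndarray"                       # (n, n), same order
    covariates: Optional[CovariateMatrix] = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        n = self.genotype.n_samples
        if len(self.phenotype.values) != n or self.kinship.shape != (n, n):
            raise DataError("aligned members disagree on sample count")
        if np.any(np.isnan(self.phenotype.values)):
            raise DataError("aligned phenotype contains missing values")
        if len(np.unique(self.phenotype.values)) < 2:
            raise DataError("phenotype has fewer than 2 distinct values")
        c = self.n_fixed_effects
        if n < c + 2:
            raise DataError(f"n={n} too small for c={c} fixed effects (need n >= c+2)")

    @property
    def n_samples(self) -> int:
        return self.genotype.n_samples

    @property
    def n_fixed_effects(self) -> int:
        """c = intercept + covariates + one marker."""
        k = 0 if self.covariates is None else self.covariates.values.shape[1]
        return k + 2

    def null_design(self) -> np.ndarray:
        """Intercept + covariates, the fixed effects shared by every marker model."""
        n = self.n_samples
        cols = [np.ones((n, 1))]
        if self.covariates is not None:
            cols.append(self.covariates.values)
        return np.hstack(cols)


# ---------------------------------------------------------------------------
# genotype readers


def _metadata_from_marker_ids(marker_ids: Sequence[str]):
    chroms, positions = [], []
    for i, mid in enumerate(marker_ids):
        match = _MARKER_ID_RE.match(str(mid))
        if match is None:
            return (np.array(["1"] * len(marker_ids)),
                    np.arange(1, len(marker_ids) + 1, dtype=np.int64))
        chroms.append(match.group("chrom"))
        positions.append(int(match.group("pos")))
    return np.asarray(chroms, dtype=str), np.asarray(positions, dtype=np.int64)


def _mean_impute(dosages: np.ndarray) -> np.ndarray:
    if not np.any(np.isnan(dosages)):
        return dosages
    col_mean = np.nanmean(dosages, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(dosages))
    dosages[idx] = col_mean[idx[1]]
    return dosages


def _sort_by_position(geno: GenotypeMatrix) -> GenotypeMatrix:
    order = np.lexsort((geno.positions, geno.chromosomes))
    if np.array_equal(order, np.arange(geno.n_markers)):
        return geno
    return geno.subset_markers(order)


def read_genotype(path: str | Path, fmt: Optional[str] = None) -> GenotypeMatrix:
    """Read a genotype matrix from CSV, HDF5 or PLINK bed/bim/fam.

    ``fmt`` is one of ``{"csv", "hdf5", "plink"}``; when omitted it is
    inferred from the file suffix.  Markers are sorted by (chromosome,
    position) after loading.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".csv": "csv", ".h5": "hdf5", ".hdf5": "hdf5", ".bed": "plink"}.get(suffix)
        if fmt is None:
            raise DataError(f"cannot infer genotype format from suffix {suffix!r}")
    if fmt == "csv":
        geno = _read_genotype_csv(path)
    elif fmt == "hdf5":
        geno = _read_genotype_hdf5(path)
    elif fmt == "plink":
        geno = _read_genotype_plink(path)
    else:
        raise DataError(f"unknown genotype format {fmt!r}")
    return _sort_by_position(geno)


def _read_genotype_csv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - message path
        raise DataError(f"unreadable genotype CSV {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise DataError("genotype CSV has no marker columns")
    dosages = df.to_numpy(dtype=np.float64)
    dosages = _mean_impute(dosages)
    marker_ids = df.columns.to_numpy(dtype=str)
    chroms, positions = _metadata_from_marker_ids(marker_ids)
    return GenotypeMatrix(df.index.to_numpy(dtype=str), dosages, marker_ids, chroms, positions)


def _read_genotype_hdf5(path: Path) -> GenotypeMatrix:
    with h5py.File(path, "r") as f:
        for key in ("sample_ids", "marker_ids", "chromosomes", "positions", "dosages"):
            if key not in f:
                raise DataError(f"HDF5 genotype file missing dataset {key!r}")
        sample_ids = f["sample_ids"].asstr()[:]
        marker_ids = f["marker_ids"].asstr()[:]
        chroms = f["chromosomes"].asstr()[:]
        positions = f["positions"][:]
        dosages = _mean_impute(f["dosages"][:].astype(np.float64))
    return GenotypeMatrix(sample_ids, dosages, marker_ids, chroms, positions)


def _read_genotype_plink(bed_path: Path) -> GenotypeMatrix:
    bed_path = bed_path.with_suffix(".bed")
    bim_path = bed_path.with_suffix(".bim")
    fam_path = bed_path.with_suffix(".fam")
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str, "fid": str})
    try:
        bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                          names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                          dtype={"chrom": str, "snp": str})
    except pd.errors.EmptyDataError:
        raise DataError(f"bim file {bim_path} lists no markers")
    n, m = len(fam), len(bim)
    if m == 0:
        raise DataError(f"bim file {bim_path} lists no markers")
    raw = bed_path.read_bytes()
    if raw[:2] != _PLINK_MAGIC:
        raise DataError(f"{bed_path} lacks PLINK bed magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise DataError("only SNP-major bed files are supported")
    bytes_per_marker = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_marker * m:
        raise DataError(f"bed payload size inconsistent with {n} samples x {m} markers")
    body = body.reshape(m, bytes_per_marker)
    # unpack 2-bit codes, sample-fastest within byte (little-endian pairs)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T.copy()        # (n, m) counts of A1
    dosages = _mean_impute(dosages)
    # flip so dosage counts the minor allele
    freq = dosages.mean(axis=0) / 2.0
    flip = freq > 0.5
    if np.any(flip):
        dosages[:, flip] = 2.0 - dosages[:, flip]
        logger.info("flipped %d markers so dosage counts the minor allele", int(flip.sum()))
    return GenotypeMatrix(fam["iid"].to_numpy(dtype=str), dosages,
                          bim["snp"].to_numpy(dtype=str),
                          bim["chrom"].to_numpy(dtype=str),
                          bim["pos"].to_numpy(dtype=np.int64))


# ---------------------------------------------------------------------------
# genotype writers (CSV/HDF5 round-trip; PLINK writer used to build fixtures)


def write_genotype_csv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.sample_ids, columns=geno.marker_ids)
    df.index.name = "sample_id"
    df.to_csv(path)


def write_genotype_hdf5(geno: GenotypeMatrix, path: str | Path, chunk_markers: int = 1000) -> None:
    with h5py.File(path, "w") as f:
        str_dt = h5py.string_dtype()
        f.create_dataset("sample_ids", data=geno.sample_ids.astype(object), dtype=str_dt)
        f.create_dataset("marker_ids", data=geno.marker_ids.astype(object), dtype=str_dt)
        f.create_dataset("chromosomes", data=geno.chromosomes.astype(object), dtype=str_dt)
        f.create_dataset("positions", data=geno.positions)
        chunks = (geno.n_samples, min(chunk_markers, geno.n_markers))
        f.create_dataset("dosages", data=geno.dosages, chunks=chunks)


def write_genotype_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK 1.9 bed/bim/fam triplet (hard calls only).

    A1 is the minor allele, so dosages round-trip unchanged through
    :func:`read_genotype`.
    """
    prefix = Path(prefix)
    dosages = geno.dosages
    if not np.allclose(dosages, np.round(dosages)):
        raise DataError("PLINK bed stores hard calls; dosages must be integral")
    n, m = dosages.shape
    with open(prefix.with_suffix(".fam"), "w") as f:
        for sid in geno.sample_ids:
            f.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as f:
        for j in range(m):
            f.write(f"{geno.chromosomes[j]} {geno.marker_ids[j]} 0 {geno.positions[j]} A G\n")
    code = np.array([3, 2, 0], dtype=np.uint8)       # dosage 0/1/2 -> bed code
    codes = code[np.round(dosages).astype(int).T]    # (m, n)
    bytes_per_marker = (n + 3) // 4
    padded = np.zeros((m, bytes_per_marker * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (padded.reshape(m, bytes_per_marker, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)).sum(
        axis=2, dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as f:
        f.write(_PLINK_MAGIC + bytes([_SNP_MAJOR]))
        f.write(packed.tobytes())


# ---------------------------------------------------------------------------
# phenotype / covariates


def read_phenotype(path: str | Path, trait_name: str) -> PhenotypeVector:
    """Read one trait from a phenotype CSV (sample-id column + trait columns).

    Replicate rows for one sample are averaged (missing replicates ignored);
    samples whose every replicate is missing stay flagged as NaN.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise DataError("phenotype CSV needs a sample-id column and at least one trait")
    id_col = df.columns[0]
    if trait_name not in df.columns[1:]:
        available = ", ".join(df.columns[1:])
        raise DataError(f"trait {trait_name!r} not found; available traits: {available}")
    sub = df[[id_col, trait_name]].copy()
    sub[trait_name] = pd.to_numeric(sub[trait_name], errors="coerce")
    if sub[trait_name].notna().sum() == 0:
        raise DataError(f"trait {trait_name!r} has zero parsable values")
    n_dup = sub[id_col].duplicated().sum()
    grouped = sub.groupby(id_col, sort=False)[trait_name].mean()
    if n_dup:
        logger.info("phenotype %r: averaged replicates for %d duplicated sample ids",
                    trait_name, int(n_dup))
    return PhenotypeVector(grouped.index.to_numpy(dtype=str),
                           grouped.to_numpy(dtype=np.float64), trait_name)


def read_covariates(path: str | Path) -> CovariateMatrix:
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise DataError("covariate CSV needs a sample-id column and at least one covariate")
    values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return CovariateMatrix(df.iloc[:, 0].to_numpy(dtype=str), values,
                           df.columns[1:].to_numpy(dtype=str))


# ---------------------------------------------------------------------------
# alignment and filtering


def align_samples(genotype: GenotypeMatrix,
                  phenotype: PhenotypeVector,
                  kinship,
                  covariates: Optional[CovariateMatrix] = None) -> AlignedDataset:
    """Restrict all inputs to common samples in genotype-file order.

    Samples missing the phenotype (NaN) or any covariate are dropped.
    ``kinship`` is a :class:`~permlmm.kinship.KinshipMatrix`.
    """
    common = set(genotype.sample_ids) & set(phenotype.sample_ids) & set(kinship.sample_ids)
    if covariates is not None:
        common &= set(covariates.sample_ids)

    pheno_map = dict(zip(phenotype.sample_ids, phenotype.values))
    usable = {s for s in common if np.isfinite(pheno_map[s])}
    if covariates is not None:
        cov_map = {s: row for s, row in zip(covariates.sample_ids, covariates.values)}
        usable = {s for s in usable if np.all(np.isfinite(cov_map[s]))}

    # canonical order: genotype-file order restricted to the usable intersection
    keep = [i for i, s in enumerate(genotype.sample_ids) if s in usable]
    ordered_ids = genotype.sample_ids[keep]
    n_dropped = len(genotype.sample_ids) - len(keep)
    if n_dropped:
        logger.info("align_samples: dropped %d of %d genotyped samples",
                    n_dropped, len(genotype.sample_ids))

    k = 0 if covariates is None else covariates.values.shape[1]
    if len(keep) < k + 4:
        raise DataError(f"only {len(keep)} usable samples for {k + 2} fixed effects")

    geno = genotype.subset_samples(np.asarray(keep, dtype=int))
    pheno = PhenotypeVector(ordered_ids,
                            np.array([pheno_map[s] for s in ordered_ids]),
                            phenotype.trait_name)
    kin_index = {s: i for i, s in enumerate(kinship.sample_ids)}
    kidx = np.array([kin_index[s] for s in ordered_ids], dtype=int)
    K = kinship.values[np.ix_(kidx, kidx)]
    cov = None
    if covariates is not None:
        cov = CovariateMatrix(ordered_ids,
                              np.vstack([cov_map[s] for s in ordered_ids]),
                              covariates.names)
        if np.linalg.matrix_rank(np.hstack([np.ones((len(keep), 1)), cov.values])) < k + 1:
            raise DataError("covariates rank-deficient after alignment")
    return AlignedDataset(geno, pheno, K, cov, n_dropped=n_dropped)


def filter_maf(genotype: GenotypeMatrix, maf_min: float = 0.0, mac_min: int = 0) -> GenotypeMatrix:
    """Drop markers below a minor-allele frequency or count threshold."""
    if not 0.0 <= maf_min <= 0.5:
        raise DataError("maf_min must be in [0, 0.5]")
    if mac_min < 0:
        raise DataError("mac_min must be non-negative")
    keep = (genotype.maf() >= maf_min) & (genotype.mac() >= mac_min)
    if maf_min > 0:
        keep &= genotype.maf() > 0
    if not np.any(keep):
        raise DataError("all markers removed by MAF/MAC filter")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_maf: removed %d of %d markers (maf>=%.4g, mac>=%d)",
                    n_removed, genotype.n_markers, maf_min, mac_min)
    return genotype.subset_markers(np.where(keep)[0])


# ---------------------------------------------------------------------------
# results


def write_results(scan_result, path: str | Path, thresholds=None,
                  summary_path: str | Path | None = None, seed=None) -> None:
    """Write the per-marker scan table as CSV plus a JSON side-car summary.

    ``scan_result`` is a :class:`~permlmm.lmm.ScanResult`; ``thresholds`` an
    optional :class:`~permlmm.permutation.ThresholdResult`.
    """
    path = Path(path)
    df = scan_result.to_frame()
    df.to_csv(path, index=False, float_format="%.12g")
    summary = {
        "n_samples": scan_result.n_samples,
        "n_fixed_effects": scan_result.n_fixed_effects,
        "n_markers_tested": int(np.isfinite(scan_result.pvalues).sum()),
        "sigma_g2": scan_result.sigma_g2,
        "sigma_e2": scan_result.sigma_e2,
        "seed": seed,
    }
    if thresholds is not None:
        summary.update({
            "alpha": thresholds.alpha,
            "bonferroni_threshold": thresholds.bonferroni,
            "permutation_threshold": thresholds.maxt,
            "n_permutations": thresholds.q,
            "p_min_per_permutation": (None if thresholds.p_min is None
                                      else [float(x) for x in thresholds.p_min]),
        })
    if summary_path is None:
        summary_path = path.with_suffix(".summary.json")
    with open(summary_path, "w") as f:
        json.dump(summary, f, indent=2)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"marker_id": str, "chromosome": str})
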