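"""Linear mixed model core: variance components, whitening, batched F-tests.

Model
-----
For each marker j the phenotype is modelled as

    y = X_j beta + u + eps,   u ~ N(0, sigma_g^2 K),  eps ~ N(0, sigma_e^2 I),

where X_j stacks an intercept, optional covariates and the marker dosage
(c columns in total).  The variance components are estimated once, on the
null model without any marker, by maximum likelihood; they are reused for
every marker's alternative model.  With V = sigma_g^2 K + sigma_e^2 I and
its Cholesky factor V = C C^T, pre-multiplying the design and phenotype by
C^{-1} (whitening) turns generalized least squares into ordinary least
squares, so marker batches can be tested with one batched OLS solve.  The
marker test is the F-test of the alternative against the null:

    t_j = (n - c) (RSS_0 - RSS_j) / RSS_j  ~  F(1, n - c)  under H0.

Variance-component optimisation profiles out beta and the total variance
analytically on the eigenbasis of K and searches the single ratio
delta = sigma_e^2 / sigma_g^2 on a dense log grid with local refinement
(the FaST-LMM / EMMAX single-kinship strategy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .data_io import AlignedDataset, DataError, GenotypeMatrix

__all__ = [
    "VarianceComponents", "CovarianceModel", "BatchRegressionResult", "ScanResult",
    "estimate_variance_components", "whiten", "batch_ols",
    "f_statistic", "f_pvalue", "gwas_scan",
]

_LOG10_DELTA_RANGE = (-5.0, 5.0)
_N_GRID = 100
_LOG_DELTA_TOL = 1e-6
_COND_MAX = 1e10


@dataclass
class VarianceComponents:
    """ML (or REML) estimates of the genetic and residual variances."""

    sigma_g2: float
    sigma_e2: float
    log_likelihood: float
    method: str = "ml"

    @property
    def heritability(self) -> float:
        """Narrow-sense ratio sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


@dataclass
class CovarianceModel:
    """V = sigma_g^2 K + sigma_e^2 I together with its Cholesky factor."""

    V: np.ndarray
    C: np.ndarray               # lower triangular, V = C C^T

    @classmethod
    def from_components(cls, vc: VarianceComponents, K: np.ndarray) -> "CovarianceModel":
        V = vc.sigma_g2 * K + vc.sigma_e2 * np.eye(len(K))
        return cls(V, _chol_with_jitter(V))


def _chol_with_jitter(V: np.ndarray) -> np.ndarray:
    for ridge in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(V if ridge == 0.0 else V + ridge * np.eye(len(V)))
        except np.linalg.LinAlgError:
            continue
    raise DataError("covariance matrix V is not positive definite")


def whiten(model: CovarianceModel, data: np.ndarray) -> np.ndarray:
    """Apply C^{-1} by triangular forward-substitution (no explicit inverse)."""
    arr = np.asarray(data, dtype=np.float64)
    if arr.shape[0] != model.C.shape[0]:
        raise DataError(f"cannot whiten shape {arr.shape} with n={model.C.shape[0]}")
    return solve_triangular(model.C, arr, lower=True)


# ---------------------------------------------------------------------------
# variance components


def eigendecompose_kinship(K: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition K = U diag(S) U^T, eigenvalues clipped at 0.

    Computed once per dataset and shared by the null fit and by every
    per-permutation refit.
    """
    S, U = np.linalg.eigh(K)
    return np.maximum(S, 0.0), U


def _profile_loglik(log10_delta: float, ystar: np.ndarray, Xstar: np.ndarray,
                    S: np.ndarray, reml: bool) -> Tuple[float, float, np.ndarray]:
    """Profile log-likelihood at delta; returns (ll, sigma_g2, beta)."""
    n, p = Xstar.shape
    D = S + 10.0 ** log10_delta
    Xw = Xstar / D[:, None]
    XtDX = Xstar.T @ Xw
    XtDy = Xw.T @ ystar
    beta = np.linalg.solve(XtDX, XtDy)
    r = ystar - Xstar @ beta
    rss_w = float(np.sum(r * r / D))
    logdetD = float(np.sum(np.log(D)))
    if reml:
        df = n - p
        sigma_g2 = rss_w / df
        sign, logdet_xx = np.linalg.slogdet(Xstar.T @ Xstar)
        sign2, logdet_xdx = np.linalg.slogdet(XtDX)
        ll = -0.5 * (df * np.log(2.0 * np.pi * sigma_g2) + logdetD
                     + logdet_xdx - logdet_xx + df)
    else:
        sigma_g2 = rss_w / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma_g2) + logdetD + n)
    return ll, sigma_g2, beta


def estimate_variance_components(y: np.ndarray,
                                 null_design: np.ndarray,
                                 K: np.ndarray,
                                 method: str = "ml",
                                 eig: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                                 ) -> VarianceComponents:
    """Fit (sigma_g2, sigma_e2) on the null model y = X0 beta + u + eps.

    Parameters
    ----------
    y : phenotype, no missing values.
    null_design : intercept + covariates only (never a marker column).
    K : kinship matrix aligned to ``y``.
    method : "ml" (default) or "reml".
    eig : optional precomputed ``eigendecompose_kinship(K)`` to share
        across permutation refits.
    """
    y = np.asarray(y, dtype=np.float64)
    X0 = np.atleast_2d(np.asarray(null_design, dtype=np.float64))
    if y.ndim != 1 or len(y) != X0.shape[0] or K.shape != (len(y), len(y)):
        raise DataError("variance-component inputs misaligned")
    if np.ptp(y) == 0.0:
        raise DataError("phenotype is constant; variance components undefined")
    reml = method.lower() == "reml"
    if eig is None:
        eig = eigendecompose_kinship(K)
    S, U = eig
    ystar = U.T @ y
    Xstar = U.T @ X0

    lo, hi = _LOG10_DELTA_RANGE
    grid = np.linspace(lo, hi, _N_GRID)
    lls = np.array([_profile_loglik(g, ystar, Xstar, S, reml)[0] for g in grid])
    best = int(np.argmax(lls))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_profile_loglik(g, ystar, Xstar, S, reml)[0],
        bounds=(a, b), method="bounded",
        options={"xatol": _LOG_DELTA_TOL})
    log10_delta = float(res.x) if -res.fun >= lls[best] else grid[best]
    ll, sigma_g2, _ = _profile_loglik(log10_delta, ystar, Xstar, S, reml)
    delta = 10.0 ** log10_delta
    return VarianceComponents(sigma_g2=sigma_g2, sigma_e2=delta * sigma_g2,
                              log_likelihood=ll, method="reml" if reml else "ml")


# ---------------------------------------------------------------------------
# batched OLS


@dataclass
class BatchRegressionResult:
    """Per-block OLS solutions for a batch of marker design blocks."""

    coefficients: np.ndarray     # (b, c), NaN where flagged
    rss: np.ndarray              # (b,)
    se_marker: np.ndarray        # (b,) std. error of the last (marker) column
    flagged: np.ndarray          # (b,) bool, rank-deficient blocks


def batch_ols(design_blocks: np.ndarray, whitened_y: np.ndarray) -> BatchRegressionResult:
    """Solve b independent OLS problems sharing shapes (b, n, c).

    ``whitened_y`` may be a single vector (n,) broadcast over blocks, or a
    (b, n) matrix with one response per block (used by the permutation
    engine, where the 4D permutation x marker tensor is flattened onto the
    leading block axis).  Rank-deficient blocks (marker collinear with the
    intercept/covariates, e.g. monomorphic markers) are flagged, not fatal.
    """
    Xt = np.asarray(design_blocks, dtype=np.float64)
    if Xt.ndim != 3:
        raise DataError("design_blocks must have shape (b, n, c)")
    b, n, c = Xt.shape
    Y = np.asarray(whitened_y, dtype=np.float64)
    if Y.ndim == 1:
        if len(Y) != n:
            raise DataError("whitened_y length mismatch")
        Y = np.broadcast_to(Y, (b, n))
    elif Y.shape != (b, n):
        raise DataError(f"whitened_y shape {Y.shape} incompatible with blocks {Xt.shape}")

    G = np.einsum("bnc,bnd->bcd", Xt, Xt, optimize=True)
    g = np.einsum("bnc,bn->bc", Xt, Y, optimize=True)

    ev = np.linalg.eigvalsh(G)
    flagged = (ev[:, 0] <= 0) | (ev[:, -1] / np.maximum(ev[:, 0], 1e-300) > _COND_MAX)

    coef = np.full((b, c), np.nan)
    rss = np.full(b, np.nan)
    se = np.full(b, np.nan)
    ok = ~flagged
    if np.any(ok):
        coef[ok] = np.linalg.solve(G[ok], g[ok][..., None])[..., 0]
        resid = Y[ok] - np.einsum("bnc,bc->bn", Xt[ok], coef[ok], optimize=True)
        rss[ok] = np.einsum("bn,bn->b", resid, resid, optimize=True)
        e_last = np.zeros((int(ok.sum()), c))
        e_last[:, -1] = 1.0
        inv_last = np.linalg.solve(G[ok], e_last[..., None])[:, -1, 0]
        if n > c:
            se[ok] = np.sqrt(np.maximum(rss[ok], 0.0) / (n - c) * inv_last)
    return BatchRegressionResult(coef, rss, se, flagged)


def f_statistic(rss0: np.ndarray | float, rss: np.ndarray | float,
                n: int, c: int) -> np.ndarray | float:
    """t = (n - c)(RSS0 - RSS)/RSS; negatives from round-off clipped to 0.

    A saturated fit (RSS == 0) yields +inf, flagged by the caller.
    """
    if n <= c:
        raise DataError(f"n={n} must exceed c={c}")
    rss0 = np.asarray(rss0, dtype=np.float64)
    rss = np.asarray(rss, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (n - c) * (rss0 - rss) / rss
        t = np.where(rss == 0.0, np.inf, t)
    t = np.maximum(t, 0.0)
    return float(t) if t.ndim == 0 else t


def f_pvalue(t: np.ndarray | float, n: int, c: int) -> np.ndarray | float:
    """Upper tail of F(1, n - c) at t."""
    if n <= c:
        raise DataError(f"n={n} must exceed c={c}")
    p = stats.f.sf(t, 1, n - c)
    return float(p) if np.ndim(t) == 0 else p


# ---------------------------------------------------------------------------
# full scan


@dataclass
class ScanResult:
    """Per-marker association results plus the null-model fit."""

    marker_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    maf: np.ndarray
    effects: np.ndarray
    std_errors: np.ndarray
    statistics: np.ndarray        # NaN where flagged
    pvalues: np.ndarray           # NaN where flagged
    n_samples: int
    n_fixed_effects: int
    sigma_g2: float
    sigma_e2: float
    log_likelihood: float
    rss0: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids,
            "chromosome": self.chromosomes,
            "position": self.positions,
            "maf": self.maf,
            "effect": self.effects,
            "std_error": self.std_errors,
            "statistic": self.statistics,
            "pvalue": self.pvalues,
        })


def _null_fit(model: CovarianceModel, y: np.ndarray, X0: np.ndarray):
    """Whitened null-model OLS; returns (yt, X0t, rss0)."""
    yt = whiten(model, y)
    X0t = whiten(model, X0)
    beta0, rss0_arr, rank, _ = np.linalg.lstsq(X0t, yt, rcond=None)
    if rank < X0.shape[1]:
        raise DataError("null design rank-deficient after whitening")
    resid0 = yt - X0t @ beta0
    return yt, X0t, float(resid0 @ resid0)


def _scan_statistics(yt: np.ndarray, X0t: np.ndarray, rss0: float,
                     whitened_markers: np.ndarray, n: int, c: int,
                     batch_size: int, backend: str):
    """Statistics for all whitened marker columns; returns per-marker arrays."""
    m = whitened_markers.shape[1]
    effects = np.full(m, np.nan)
    ses = np.full(m, np.nan)
    stats_ = np.full(m, np.nan)
    for start in range(0, m, batch_size):
        stop = min(start + batch_size, m)
        chunk = whitened_markers[:, start:stop]
        b = stop - start
        if backend == "loop":
            for j in range(b):
                blk = np.concatenate([X0t, chunk[:, j:j + 1]], axis=1)[None]
                res = batch_ols(blk, yt)
                if not res.flagged[0]:
                    effects[start + j] = res.coefficients[0, -1]
                    ses[start + j] = res.se_marker[0]
                    stats_[start + j] = f_statistic(rss0, res.rss[0], n, c)
        else:
            blocks = np.empty((b, n, c))
            blocks[:, :, :-1] = X0t[None]
            blocks[:, :, -1] = chunk.T
            res = batch_ols(blocks, yt)
            ok = ~res.flagged
            effects[start:stop][ok] = res.coefficients[ok, -1]
            ses[start:stop][ok] = res.se_marker[ok]
            stats_[start:stop][ok] = f_statistic(rss0, res.rss[ok], n, c)
    return effects, ses, stats_


def gwas_scan(dataset: AlignedDataset, batch_size: int = 50_000,
              method: str = "ml", backend: str = "batched",
              vc: Optional[VarianceComponents] = None) -> ScanResult:
    """Batched univariate LMM scan over every marker in the dataset.

    The null variance components are estimated once (or supplied via
    ``vc``), the data whitened by the Cholesky factor of V, and markers
    tested in batches of ``batch_size``.  ``backend`` selects the batched
    tensor path (default) or a per-marker loop; both give identical results
    and exist so the equivalence is testable.
    """
    if batch_size < 1:
        raise DataError("batch_size must be >= 1")
    if backend not in ("batched", "loop"):
        raise DataError(f"unknown backend {backend!r}")
    y = dataset.phenotype.values
    X0 = dataset.null_design()
    K = dataset.kinship
    n = dataset.n_samples
    c = dataset.n_fixed_effects
    if vc is None:
        vc = estimate_variance_components(y, X0, K, method=method)
    model = CovarianceModel.from_components(vc, K)
    yt, X0t, rss0 = _null_fit(model, y, X0)
    whitened_markers = whiten(model, dataset.genotype.dosages)
    effects, ses, stats_ = _scan_statistics(yt, X0t, rss0, whitened_markers,
                                            n, c, batch_size, backend)
    pvals = np.full_like(stats_, np.nan)
    finite = np.isfinite(stats_)
    pvals[finite] = f_pvalue(stats_[finite], n, c)
    geno = dataset.genotype
    return ScanResult(geno.marker_ids, geno.chromosomes, geno.positions, geno.maf(),
                      effects, ses, stats_, pvals, n, c,
                      vc.sigma_g2, vc.sigma_e2, vc.log_likelihood, rss0)


def gwas_scan_hdf5(path, phenotype, kinship, covariates=None,
                   batch_size: int = 50_000, chunk_size: int = 10_000,
                   maf_min: float = 0.0, mac_min: int = 0,
                   method: str = "ml") -> ScanResult:
    """Scan an HDF5 genotype file chunk-wise against a precomputed kinship.

    Only marker chunks of ``chunk_size`` columns are resident at any time,
    so the full dosage matrix never needs to fit in memory.  Samples are
    aligned exactly as :func:`permlmm.data_io.align_samples` would; results
    match the in-memory scan bit for bit.
    """
    import h5py

    from .data_io import PhenotypeVector, _mean_impute

    with h5py.File(path, "r") as f:
        sample_ids = f["sample_ids"].asstr()[:]
        marker_ids = f["marker_ids"].asstr()[:]
        chroms = f["chromosomes"].asstr()[:]
        positions = f["positions"][:]

        pheno_map = dict(zip(phenotype.sample_ids, phenotype.values))
        kin_index = {s: i for i, s in enumerate(kinship.sample_ids)}
        keep = [i for i, s in enumerate(sample_ids)
                if s in pheno_map and np.isfinite(pheno_map[s]) and s in kin_index]
        ids = sample_ids[keep]
        n = len(ids)
        y = np.array([pheno_map[s] for s in ids])
        kidx = np.array([kin_index[s] for s in ids], dtype=int)
        K = kinship.values[np.ix_(kidx, kidx)]
        if covariates is not None:
            cov_map = {s: r for s, r in zip(covariates.sample_ids, covariates.values)}
            X0 = np.hstack([np.ones((n, 1)), np.vstack([cov_map[s] for s in ids])])
        else:
            X0 = np.ones((n, 1))
        c = X0.shape[1] + 1
        if n < c + 2:
            raise DataError(f"only {n} aligned samples for c={c} fixed effects")

        vc = estimate_variance_components(y, X0, K, method=method)
        model = CovarianceModel.from_components(vc, K)
        yt, X0t, rss0 = _null_fit(model, y, X0)

        keep_arr = np.asarray(keep, dtype=int)
        m_total = len(marker_ids)
        kept_cols, mafs, eff_l, se_l, st_l = [], [], [], [], []
        for start in range(0, m_total, chunk_size):
            stop = min(start + chunk_size, m_total)
            chunk = f["dosages"][:, start:stop][keep_arr].astype(np.float64)
            chunk = _mean_impute(chunk)
            p = chunk.mean(axis=0) / 2.0
            maf = np.minimum(p, 1.0 - p)
            counts = chunk.sum(axis=0)
            mac = np.minimum(counts, 2.0 * n - counts)
            ok = (maf >= maf_min) & (mac >= mac_min)
            if maf_min > 0:
                ok &= maf > 0
            if not np.any(ok):
                continue
            cols = np.where(ok)[0]
            wm = whiten(model, chunk[:, cols])
            eff, se, st = _scan_statistics(yt, X0t, rss0, wm, n, c,
                                           batch_size, "batched")
            kept_cols.append(cols + start)
            mafs.append(maf[cols])
            eff_l.append(eff)
            se_l.append(se)
            st_l.append(st)
    if not kept_cols:
        raise DataError("all markers removed by MAF/MAC filter")
    idx = np.concatenate(kept_cols)
    stats_ = np.concatenate(st_l)
    pvals = np.full_like(stats_, np.nan)
    finite = np.isfinite(stats_)
    pvals[finite] = f_pvalue(stats_[finite], n, c)
    return ScanResult(marker_ids[idx], chroms[idx], positions[idx],
                      np.concatenate(mafs), np.concatenate(eff_l),
                      np.concatenate(se_l), stats_, pvals, n, c,
                      vc.sigma_g2, vc.sigma_e2, vc.log_likelihood, rss0)
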