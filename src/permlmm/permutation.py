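"""Westfall-Young maxT permutation thresholds for the batched LMM scan.

The phenotype is permuted q times against fixed genotype, covariates and
kinship.  For each permutation the null variance components are
re-estimated (the permuted phenotype has its own polygenic fit), the data
re-whitened with the permutation-specific Cholesky factor, and the full
marker scan repeated.  Per permutation k the maximal statistic (k)t_max
and the corresponding minimal p-value (k)p_min are recorded; the
alpha-quantile (k-th order statistic, k = max(1, floor(alpha q))) of the
(k)p_min is the maxT significance threshold delta* that controls the
family-wise error rate at level alpha.  Two flavours of adjusted p-value
are provided: the maxT-adjusted p~_j (fraction of permutations whose
t_max beats t_j) and the pooled permutation p-value that ranks t_j within
the entire q x m permuted null distribution.

Permutations are processed in groups: the group's whitened designs form a
(group x batch x n x c) tensor whose leading axes are flattened onto the
block axis of the batched OLS kernel, so memory stays O(group * batch * n * c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_io import AlignedDataset, DataError
from .lmm import (CovarianceModel, batch_ols, eigendecompose_kinship,
                  estimate_variance_components, f_pvalue, f_statistic,
                  whiten, _null_fit, ScanResult)

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationSet", "PermutationScan", "ThresholdResult",
    "generate_permutations", "permutation_scan", "maxt_threshold",
    "westfall_young_adjusted", "pooled_adjusted_pvalues",
    "bonferroni_threshold", "compute_thresholds",
]


@dataclass
class PermutationSet:
    """q seeded uniform permutations of the sample indices 0..n-1."""

    n: int
    q: int
    seed: int
    indices: np.ndarray          # (q, n) int

    def __post_init__(self) -> None:
        if self.indices.shape != (self.q, self.n):
            raise DataError("permutation index array has wrong shape")


def generate_permutations(n: int, q: int, seed: int) -> PermutationSet:
    """Draw q independent uniform permutations from a seeded PCG64 stream.

    All permutations are drawn up-front from one generator, so the set is a
    pure function of (n, q, seed) regardless of how the scan later batches
    them.
    """
    if n < 2:
        raise DataError("need n >= 2 to permute")
    if q < 1:
        raise DataError("need q >= 1 permutations")
    rng = np.random.default_rng(seed)
    idx = np.array([rng.permutation(n) for _ in range(q)], dtype=np.intp)
    return PermutationSet(n=n, q=q, seed=seed, indices=idx)


@dataclass
class PermutationScan:
    """q x m permuted statistics with per-permutation summaries."""

    statistics: np.ndarray       # (q, m), NaN for flagged markers / failed rows
    sigma_g2: np.ndarray         # (q,)
    sigma_e2: np.ndarray         # (q,)
    t_max: np.ndarray            # (q,)
    p_min: np.ndarray            # (q,)
    failed: np.ndarray           # (q,) bool, variance-component failures
    n_samples: int
    n_fixed_effects: int


@dataclass
class ThresholdResult:
    """Significance thresholds at level alpha for one scan."""

    alpha: float
    m_tested: int
    bonferroni: float
    maxt: Optional[float] = None
    q: int = 0
    p_min: Optional[np.ndarray] = None


def permutation_scan(dataset: AlignedDataset, permutations: PermutationSet,
                     batch_size: int = 50_000, perm_batch_size: int = 5,
                     method: str = "ml") -> PermutationScan:
    """Full marker scan under every phenotype permutation.

    Genotype, covariates and kinship stay fixed; only the phenotype entries
    are reordered.  Variance components are re-estimated per permutation on
    the shared eigenbasis of K.  Permutations whose variance-component
    optimisation fails are flagged and excluded from the maxima.
    """
    y = dataset.phenotype.values
    X0 = dataset.null_design()
    K = dataset.kinship
    n = dataset.n_samples
    c = dataset.n_fixed_effects
    m = dataset.genotype.n_markers
    if permutations.n != n:
        raise DataError("permutation set drawn for a different sample count")
    q = permutations.q
    eig = eigendecompose_kinship(K)
    G = dataset.genotype.dosages

    stats_all = np.full((q, m), np.nan)
    sg2 = np.full(q, np.nan)
    se2 = np.full(q, np.nan)
    failed = np.zeros(q, dtype=bool)

    for g_start in range(0, q, perm_batch_size):
        g_stop = min(g_start + perm_batch_size, q)
        group = range(g_start, g_stop)
        yts, X0ts, rss0s, markers_w, rows = [], [], [], [], []
        for k in group:
            yk = y[permutations.indices[k]]
            try:
                vc = estimate_variance_components(yk, X0, K, method=method, eig=eig)
                model = CovarianceModel.from_components(vc, K)
                yt, X0t, rss0 = _null_fit(model, yk, X0)
            except (DataError, np.linalg.LinAlgError) as exc:
                failed[k] = True
                logger.warning("permutation %d failed variance-component fit: %s", k, exc)
                continue
            sg2[k], se2[k] = vc.sigma_g2, vc.sigma_e2
            yts.append(yt)
            X0ts.append(X0t)
            rss0s.append(rss0)
            markers_w.append(whiten(model, G))
            rows.append(k)
        if not rows:
            continue
        g = len(rows)
        rss0_arr = np.asarray(rss0s)
        for start in range(0, m, batch_size):
            stop = min(start + batch_size, m)
            b = stop - start
            # 4D tensor (g, b, n, c): group's whitened designs, flattened
            # onto the block axis of the batched OLS kernel
            blocks = np.empty((g, b, n, c))
            Y = np.empty((g, b, n))
            for i in range(g):
                blocks[i, :, :, :-1] = X0ts[i][None]
                blocks[i, :, :, -1] = markers_w[i][:, start:stop].T
                Y[i] = yts[i][None]
            res = batch_ols(blocks.reshape(g * b, n, c), Y.reshape(g * b, n))
            rss = res.rss.reshape(g, b)
            flag = res.flagged.reshape(g, b)
            t = f_statistic(rss0_arr[:, None], rss, n, c)
            t[flag] = np.nan
            stats_all[rows, start:stop] = t

    with np.errstate(all="ignore"):
        t_max = np.full(q, np.nan)
        valid = ~failed
        if np.any(valid):
            t_max[valid] = np.nanmax(stats_all[valid], axis=1)
    p_min = np.full(q, np.nan)
    finite = np.isfinite(t_max)
    p_min[finite] = f_pvalue(t_max[finite], n, c)
    return PermutationScan(stats_all, sg2, se2, t_max, p_min, failed, n, c)


# ---------------------------------------------------------------------------
# thresholds and adjusted p-values


def maxt_threshold(p_min: Sequence[float], alpha: float) -> float:
    """maxT threshold: k-th smallest minimal p-value, k = max(1, floor(alpha q)).

    For alpha q < 1 the smallest p_min is returned, a deliberately
    conservative fallback for tiny permutation counts.
    """
    p = np.asarray([x for x in np.ravel(p_min) if np.isfinite(x)], dtype=np.float64)
    if p.size == 0:
        raise DataError("no minimal p-values supplied")
    if not 0.0 < alpha < 1.0:
        raise DataError("alpha must be in (0, 1)")
    k = max(1, int(np.floor(alpha * p.size)))
    return float(np.sort(p)[k - 1])


def westfall_young_adjusted(t_max: Sequence[float], observed: Sequence[float]) -> np.ndarray:
    """maxT-adjusted p~_j = #{k : (k)t_max >= t_j} / q per marker."""
    tm = np.asarray([x for x in np.ravel(t_max) if np.isfinite(x)], dtype=np.float64)
    if tm.size == 0:
        raise DataError("no permutation maxima supplied")
    obs = np.asarray(observed, dtype=np.float64)
    out = np.full(obs.shape, np.nan)
    finite = np.isfinite(obs)
    tm_sorted = np.sort(tm)
    # count of t_max >= t_j via searchsorted on the sorted maxima
    counts = tm.size - np.searchsorted(tm_sorted, obs[finite], side="left")
    out[finite] = counts / tm.size
    return out


def pooled_adjusted_pvalues(perm_statistics: np.ndarray, observed: Sequence[float],
                            smoothing: bool = False) -> np.ndarray:
    """Pooled permutation p-value per marker.

    p_j = #{(k, j') : (k)t_j' >= t_j} / N over the entire permuted q x m
    statistic matrix, with N the number of finite permuted statistics
    (q x m when nothing is flagged).  ``smoothing`` applies the optional
    add-one correction (count + 1)/(N + 1) so p-values are never exactly 0.
    """
    pool = np.ravel(np.asarray(perm_statistics, dtype=np.float64))
    pool = np.sort(pool[np.isfinite(pool)])
    if pool.size == 0:
        raise DataError("no permuted statistics supplied")
    obs = np.asarray(observed, dtype=np.float64)
    out = np.full(obs.shape, np.nan)
    finite = np.isfinite(obs)
    counts = pool.size - np.searchsorted(pool, obs[finite], side="left")
    if smoothing:
        out[finite] = (counts + 1.0) / (pool.size + 1.0)
    else:
        out[finite] = counts / pool.size
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """delta_b = alpha / m with m the number of markers actually tested."""
    if m < 1:
        raise DataError("need at least one tested marker")
    if not 0.0 < alpha < 1.0:
        raise DataError("alpha must be in (0, 1)")
    return alpha / m


def compute_thresholds(scan: ScanResult, alpha: float = 0.05,
                       perm_scan: Optional[PermutationScan] = None) -> ThresholdResult:
    """Bundle the Bonferroni and (when permutations ran) maxT thresholds."""
    m_tested = int(np.isfinite(scan.pvalues).sum())
    result = ThresholdResult(alpha=alpha, m_tested=m_tested,
                             bonferroni=bonferroni_threshold(alpha, m_tested))
    if perm_scan is not None:
        valid = np.isfinite(perm_scan.p_min)
        result.maxt = maxt_threshold(perm_scan.p_min[valid], alpha)
        result.q = int(valid.sum())
        result.p_min = perm_scan.p_min[valid]
    return result
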