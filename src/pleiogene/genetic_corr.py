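"""LD score regression: heritability, genetic correlation, trait clustering.

Univariate LD score regression models the expected association chi-square
of SNP j as ``E[chi2_j] = intercept + (N h2 / M) * l_j`` where ``l_j`` is
the LD score (sum of squared correlations with neighbouring SNPs) and M the
number of SNPs.  Polygenic signal scales with LD; confounding and sample
overlap load on the intercept.  The bivariate form regresses the product of
two traits' Z-statistics on the LD score; its slope estimates genetic
covariance and its intercept the sample-overlap term ``rho * Ns /
sqrt(N1 N2)``.  Genetic correlation is the genetic covariance normalized by
the two heritabilities.  Uncertainty comes from a delete-a-block jackknife
over contiguous SNP blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "LDScores",
    "LdscFit",
    "ClusterResult",
    "compute_ld_scores",
    "ldsc_h2",
    "ldsc_rg",
    "genomic_lambda",
    "cluster_traits",
]

_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # ~0.4549


@dataclass
class LDScores:
    """Per-SNP LD scores plus the SNP count M they were computed over."""

    table: pd.DataFrame  # snp_id, ell
    M: int


@dataclass
class LdscFit:
    """LD score regression fit (univariate or bivariate)."""

    h2: float = float("nan")
    intercept: float = float("nan")
    se_h2: float = float("nan")
    se_intercept: float = float("nan")
    lambda_gc: float = float("nan")
    gencov_slope: float = float("nan")
    rg: float = float("nan")
    gcov_intercept: float = float("nan")
    se_rg: float = float("nan")
    n_blocks_jackknife: int = 0
    flags: list = field(default_factory=list)


def compute_ld_scores(ld, window_bp: float = 10e6, n_ref: int | None = None) -> LDScores:
    """LD scores with a physical window and bias-adjusted r-squared.

    ``l_j = sum_k r~2_jk`` over SNPs k within ``window_bp`` of j (under
    block LD only same-block SNPs contribute), with the unbiased estimator
    ``r~2 = r2 - (1 - r2) / (n_ref - 2)``.  ``n_ref=None`` uses the
    panel's nominal size; ``n_ref=0`` disables the adjustment (population
    correlations known exactly).
    """
    if n_ref is None:
        n_ref = ld.n_ref
    rows = []
    for b, grp in ld.snp_index.groupby("block", sort=True):
        R = ld.blocks[b]
        pos = grp["pos"].to_numpy()
        within = np.abs(pos[:, None] - pos[None, :]) <= window_bp
        r2 = R**2
        if n_ref and n_ref > 2:
            r2 = r2 - (1.0 - r2) / (n_ref - 2)
        ell = np.sum(np.where(within, r2, 0.0), axis=1)
        rows.append(pd.DataFrame({"snp_id": grp["snp_id"].to_numpy(), "ell": ell}))
    table = pd.concat(rows, ignore_index=True)
    return LDScores(table=table, M=len(table))


def _wls_line(x, y, w):
    """Weighted least squares of y on (1, x); returns (intercept, slope)."""
    sw = w.sum()
    swx = (w * x).sum()
    swy = (w * y).sum()
    swxx = (w * x * x).sum()
    swxy = (w * x * y).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy * swxx - swx * swxy) / det
    return intercept, slope


def _block_edges(n, n_blocks):
    return np.linspace(0, n, n_blocks + 1).astype(int)


def _jackknife(theta_fn, n, n_blocks):
    """Delete-a-block jackknife: returns (estimates, se)."""
    edges = _block_edges(n, n_blocks)
    thetas = []
    for b in range(n_blocks):
        mask = np.ones(n, dtype=bool)
        mask[edges[b] : edges[b + 1]] = False
        thetas.append(theta_fn(mask))
    thetas = np.asarray(thetas)
    mean = thetas.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * np.sum((thetas - mean) ** 2, axis=0))
    return thetas, se


def _h2_weights(ell, N, h2, M):
    ellc = np.maximum(ell, 1.0)
    return 1.0 / (ellc * (1.0 + N * max(h2, 0.0) * ellc / M) ** 2)


def ldsc_h2(ss: pd.DataFrame, scores: LDScores, n_blocks: int = 200) -> LdscFit:
    """Univariate LD score regression for SNP heritability and intercept.

    Weights ``1 / (l_j (1 + N h2 l_j / M)^2)`` iterated twice from an OLS
    start; SEs by delete-a-block jackknife over contiguous SNP blocks.
    """
    merged = ss.merge(scores.table, on="snp_id")
    if len(merged) < 200:
        raise ValueError("need at least 200 SNPs for LD score regression")
    chi2 = merged["z"].to_numpy() ** 2
    ell = merged["ell"].to_numpy()
    N = float(np.nanmedian(merged["n"]))
    M = scores.M
    n = len(merged)
    if n < n_blocks:
        warnings.warn(f"reducing jackknife blocks from {n_blocks} to {n}")
        n_blocks = n

    w = np.ones(n)
    intercept = 1.0
    slope = 0.0
    for _ in range(3):  # OLS start + two weighted refits
        intercept, slope = _wls_line(ell, chi2, w)
        h2_cur = slope * M / N
        w = _h2_weights(ell, N, min(max(h2_cur, 0.0), 1.0), M)

    def theta(mask):
        i, s = _wls_line(ell[mask], chi2[mask], w[mask])
        return np.array([s * M / N, i])

    _, se = _jackknife(theta, n, n_blocks)
    return LdscFit(
        h2=slope * M / N,
        intercept=intercept,
        se_h2=float(se[0]),
        se_intercept=float(se[1]),
        lambda_gc=genomic_lambda(merged["z"].to_numpy()),
        n_blocks_jackknife=n_blocks,
    )


def ldsc_rg(
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    scores: LDScores,
    n_blocks: int = 200,
) -> LdscFit:
    """Cross-trait LD score regression for genetic correlation.

    ``E[z1_j z2_j] = gcov_intercept + (sqrt(N1 N2) rho_g / M) * l_j``;
    ``rg = rho_g / sqrt(h2_1 h2_2)`` with the heritabilities estimated by
    :func:`ldsc_h2` on the same SNPs.  The jackknife re-estimates the
    heritabilities and genetic covariance per deleted block so the rg SE
    reflects all three regressions.  ``|rg| > 1.25`` is flagged; a
    non-positive heritability leaves rg undefined (NaN, flagged).
    """
    merged = ss1.merge(ss2, on="snp_id", suffixes=("_1", "_2")).merge(
        scores.table, on="snp_id"
    )
    if len(merged) < 200:
        raise ValueError("need at least 200 SNPs for LD score regression")
    ell = merged["ell"].to_numpy()
    z1 = merged["z_1"].to_numpy()
    z2 = merged["z_2"].to_numpy()
    N1 = float(np.nanmedian(merged["n_1"]))
    N2 = float(np.nanmedian(merged["n_2"]))
    M = scores.M
    n = len(merged)
    if n < n_blocks:
        warnings.warn(f"reducing jackknife blocks from {n_blocks} to {n}")
        n_blocks = n

    def h2_fit(chi2, N, mask):
        w = np.ones(mask.sum())
        e = ell[mask]
        c = chi2[mask]
        slope = 0.0
        for _ in range(3):
            _, slope = _wls_line(e, c, w)
            w = _h2_weights(e, N, min(max(slope * M / N, 0.0), 1.0), M)
        return slope * M / N

    full = np.ones(n, dtype=bool)
    h21 = h2_fit(z1**2, N1, full)
    h22 = h2_fit(z2**2, N2, full)

    def gencov_fit(mask, h21_, h22_):
        e = ell[mask]
        y = (z1 * z2)[mask]
        ellc = np.maximum(e, 1.0)
        w = 1.0 / (
            ellc
            * (1.0 + N1 * max(h21_, 0.0) * ellc / M)
            * (1.0 + N2 * max(h22_, 0.0) * ellc / M)
        )
        icpt, slope = _wls_line(e, y, w)
        return icpt, slope * M / np.sqrt(N1 * N2)

    gcov_icpt, rho_g = gencov_fit(full, h21, h22)

    flags = []
    if h21 <= 0 or h22 <= 0:
        flags.append("nonpositive_h2")
        rg = float("nan")
        se_rg = float("nan")
    else:
        rg = rho_g / np.sqrt(h21 * h22)

        def theta(mask):
            a = h2_fit(z1**2, N1, mask)
            b = h2_fit(z2**2, N2, mask)
            _, rg_cov = gencov_fit(mask, a, b)
            if a <= 0 or b <= 0:
                return np.array([np.nan])
            return np.array([rg_cov / np.sqrt(a * b)])

        thetas, se = _jackknife(theta, n, n_blocks)
        se_rg = float(se[0]) if np.isfinite(thetas).all() else float("nan")
        if abs(rg) > 1.25:
            flags.append("rg_out_of_range")

    def icpt_theta(mask):
        i, _ = gencov_fit(mask, h21, h22)
        return np.array([i])

    _, icpt_se = _jackknife(icpt_theta, n, n_blocks)

    return LdscFit(
        h2=h21,
        gencov_slope=rho_g,
        rg=rg,
        gcov_intercept=gcov_icpt,
        se_rg=se_rg,
        se_intercept=float(icpt_se[0]),
        n_blocks_jackknife=n_blocks,
        flags=flags,
    )


def genomic_lambda(z_vec) -> float:
    """Genomic inflation factor: median chi-square over its null median."""
    z = np.asarray(z_vec, dtype=float)
    return float(np.median(z**2) / _CHI2_MEDIAN)


@dataclass
class ClusterResult:
    """Hierarchical clustering of the trait genetic-correlation matrix."""

    linkage: np.ndarray
    labels: pd.Series  # trait -> cluster id (1..k)
    k: int


def cluster_traits(rg_matrix, k: int = 3, method: str = "average") -> ClusterResult:
    """Agglomerative clustering of traits at distance ``1 - rg``.

    ``rg_matrix`` is a symmetric DataFrame (unit diagonal) or ndarray;
    missing entries are imputed as 0 with a warning.  Labels partition the
    traits into ``k`` groups; the partition is invariant to trait order.
    """
    if isinstance(rg_matrix, pd.DataFrame):
        traits = list(rg_matrix.index)
        mat = rg_matrix.to_numpy(dtype=float)
    else:
        mat = np.asarray(rg_matrix, dtype=float)
        traits = [f"trait{i + 1}" for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("rg matrix must be square")
    if k > mat.shape[0]:
        raise ValueError("k exceeds the number of traits")
    if np.isnan(mat).any():
        warnings.warn("missing rg entries imputed as 0")
        mat = np.where(np.isnan(mat), 0.0, mat)
    mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 1.0)
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    # stable order-invariant input: sort traits lexicographically
    order = np.argsort(np.asarray(traits, dtype=object))
    dist = dist[np.ix_(order, order)]
    sorted_traits = [traits[i] for i in order]
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(lab, index=sorted_traits).reindex(traits)
    return ClusterResult(linkage=Z, labels=labels, k=k)
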