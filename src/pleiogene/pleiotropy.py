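"""Composite-null pleiotropy testing and pleiotropic-gene characterization.

For a pair of traits the null hypothesis of "no pleiotropy" is composite:
either neither trait is associated with the gene (H00) or exactly one is
(H10, H01).  The alternative H11 — association with both — is what a
pleiotropic gene means.  The test statistic is the product of the two
(de-correlated) gene-level Z-scores, ``T = z1 * z2``.  Under each sub-null
T behaves like a product of independent normals whose scales reflect the
polygenic dispersion of the associated trait; the intersection-union
p-value is the maximum of the three sub-null tails, so the composite null
is rejected only when every sub-null is.

The module also houses the comparator methods (direct FDR, maximum-P), the
likelihood-ratio test for overall pleiotropy between two traits (a
four-component mixture over the p-value pairs), effect-size correlation and
Cochran's Q heterogeneity for detected genes, the hypergeometric
set-enrichment statistic, and BH / BY FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "estimate_z_correlation",
    "decorrelate_z",
    "product_normal_tail",
    "estimate_sigma_sq",
    "placo_test",
    "fdr_bh",
    "fdr_by",
    "direct_fdr_method",
    "max_p_method",
    "overall_pleiotropy_lrt",
    "effect_correlation",
    "cochran_q",
    "hypergeometric_enrichment",
    "PleioPairResult",
    "analyze_pair",
    "characterize_gene",
    "shared_gene_summary",
]

P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# de-correlation of gene Z-statistics

def estimate_z_correlation(z1_vec, z2_vec, trim_p: float = 1e-4) -> float:
    """Null correlation of gene Z-statistics across two traits.

    Sample overlap between two GWASs correlates their Z-statistics even for
    unassociated genes.  The correlation is estimated genome-wide after
    excluding genes significant in either trait (two-sided p < ``trim_p``)
    so true signal does not inflate the null estimate.
    """
    z1 = np.asarray(z1_vec, dtype=float)
    z2 = np.asarray(z2_vec, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("z vectors must be aligned")
    p1 = 2.0 * stats.norm.sf(np.abs(z1))
    p2 = 2.0 * stats.norm.sf(np.abs(z2))
    keep = np.minimum(p1, p2) >= trim_p
    if keep.sum() < 50:
        warnings.warn(
            f"only {int(keep.sum())} genes left after trimming at {trim_p}; "
            "rho_z estimate may be unstable"
        )
    if keep.sum() < 2:
        keep = np.ones_like(keep)
    return float(np.corrcoef(z1[keep], z2[keep])[0, 1])


def decorrelate_z(z1, z2, rho_z: float):
    """Whiten a pair of Z-statistics with the symmetric inverse square root.

    ``(z1*, z2*)' = R^(-1/2) (z1, z2)'`` with ``R = [[1, rho], [rho, 1]]``.
    Accepts scalars or aligned vectors.  Requires ``|rho_z| < 0.99``.
    """
    if abs(rho_z) >= 0.99:
        raise ValueError("|rho_z| >= 0.99: traits too entangled to de-correlate")
    # eigenvectors of R are fixed at (1,1)/sqrt2 and (1,-1)/sqrt2
    a = 0.5 * (1.0 / np.sqrt(1.0 + rho_z) + 1.0 / np.sqrt(1.0 - rho_z))
    b = 0.5 * (1.0 / np.sqrt(1.0 + rho_z) - 1.0 / np.sqrt(1.0 - rho_z))
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    return a * z1 + b * z2, b * z1 + a * z2


# ---------------------------------------------------------------------------
# product-normal tail

def _pn_tail_std(t: float) -> float:
    """P(|X*Y| >= t) for independent standard normals.

    The product-normal density is ``K0(|w|)/pi`` (modified Bessel function
    of the second kind).  For small t the central mass is integrated
    directly (the K0 log-singularity at 0 is integrable); for large t the
    tail is integrated on the exponentially-scaled K0 to avoid underflow.
    """
    if t == 0.0:
        return 1.0
    if t <= 1.0:
        val, _ = integrate.quad(special.k0, 0.0, t, epsabs=1e-13, limit=200)
        return float(min(max(1.0 - 2.0 * val / np.pi, P_FLOOR), 1.0))
    # tail: (2/pi) * exp(-t) * int_0^inf k0e(t+u) exp(-u) du
    val, _ = integrate.quad(
        lambda u: special.k0e(t + u) * np.exp(-u), 0.0, 60.0, epsabs=1e-13, limit=200
    )
    logp = np.log(2.0 * val / np.pi) - t
    return float(min(max(np.exp(logp), P_FLOOR), 1.0))


def product_normal_tail(t, s1: float = 1.0, s2: float = 1.0):
    """P(|X*Y| >= |t|) for independent X ~ N(0, s1^2), Y ~ N(0, s2^2).

    Uses the scaling identity ``prob(t, s1, s2) = prob(t/(s1*s2), 1, 1)``.
    Accepts a scalar or array ``t``.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("scales must be positive")
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("non-finite test statistic")
    scaled = np.abs(t_arr) / (s1 * s2)
    out = np.array([_pn_tail_std(float(x)) for x in np.atleast_1d(scaled)])
    return float(out[0]) if t_arr.ndim == 0 else out


def estimate_sigma_sq(z_vec, exclude_p: float | None = None) -> float:
    """Variance parameter of the associated-trait Z under the one-trait sub-null.

    Estimated as the marginal variance of the gene Z-statistics over all
    genes, floored at 1: for a polygenic trait the Z-scores are
    overdispersed relative to N(0,1), and that dispersion is exactly what
    the H10/H01 sub-null distributions must absorb.  ``exclude_p`` is
    accepted for interface stability but the estimator deliberately uses
    all genes.
    """
    z = np.asarray(z_vec, dtype=float)
    if z.size < 50:
        raise ValueError("need at least 50 genes to estimate sigma^2")
    return float(max(1.0, np.var(z)))


def placo_test(z1_star, z2_star, sigma1_sq: float, sigma2_sq: float):
    """Composite-null pleiotropy test on de-correlated gene Z-scores.

    ``T = z1* * z2*``; sub-null tails ``p00 = P(|XY| >= |T|)`` with unit
    scales, ``p10`` with X scaled by sigma1, ``p01`` with Y scaled by
    sigma2; the intersection-union p-value is their maximum.  Accepts
    scalars or aligned vectors; returns ``(T, p_placo)``.
    """
    if sigma1_sq < 1.0 or sigma2_sq < 1.0:
        raise ValueError("sigma^2 must be >= 1")
    z1 = np.asarray(z1_star, dtype=float)
    z2 = np.asarray(z2_star, dtype=float)
    T = z1 * z2
    p00 = product_normal_tail(T, 1.0, 1.0)
    p10 = product_normal_tail(T, np.sqrt(sigma1_sq), 1.0)
    p01 = product_normal_tail(T, 1.0, np.sqrt(sigma2_sq))
    p = np.maximum(np.maximum(p00, p10), p01)
    if T.ndim == 0:
        return float(T), float(p)
    return T, p


# ---------------------------------------------------------------------------
# FDR procedures and comparator methods

def fdr_bh(p_vec) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_vec, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fdr_by(p_vec) -> np.ndarray:
    """Benjamini-Yekutieli adjusted q-values (valid under arbitrary dependence)."""
    p = np.asarray(p_vec, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_by")[1]


def direct_fdr_method(p1_vec, p2_vec, alpha: float = 0.05) -> np.ndarray:
    """Genes separately FDR-significant in both traits (comparator method).

    Returns the boolean selection mask over the aligned gene vectors.
    """
    p1 = np.asarray(p1_vec, dtype=float)
    p2 = np.asarray(p2_vec, dtype=float)
    if p1.size == 0:
        return np.zeros(0, dtype=bool)
    return (fdr_bh(p1) < alpha) & (fdr_bh(p2) < alpha)


def max_p_method(p1_vec, p2_vec, alpha: float = 0.05) -> np.ndarray:
    """Maximum-P comparator: BH over per-gene ``max(p1, p2)``; mask of q < alpha."""
    p1 = np.asarray(p1_vec, dtype=float)
    p2 = np.asarray(p2_vec, dtype=float)
    if p1.size == 0:
        return np.zeros(0, dtype=bool)
    return fdr_bh(np.maximum(p1, p2)) < alpha


# ---------------------------------------------------------------------------
# overall-pleiotropy likelihood-ratio test

def _beta_density(p, alpha):
    return alpha * p ** (alpha - 1.0)


def _marginal_mixture_em(p, max_iter=5000, tol=1e-9):
    """Two-component (uniform + Beta(alpha,1)) EM fit for one trait's p-values.

    Densities are handled in log space so genome-wide-significant p-values
    (down to the 1e-300 floor) do not overflow ``p**(alpha-1)``.
    """
    p = np.clip(p, P_FLOOR, 1.0 - 1e-12)
    logp = np.log(p)
    q, alpha = 0.1, 0.5
    ll_old = -np.inf
    q_old, a_old = q, alpha
    for it in range(max_iter):
        # log responsibilities: alt log-density log(alpha) + (alpha-1) log p
        la = np.log(q) + np.log(alpha) + (alpha - 1.0) * logp
        l0 = np.full_like(la, np.log1p(-q))
        tot = np.logaddexp(la, l0)
        r = np.exp(la - tot)
        q = min(max(float(np.mean(r)), 1e-8), 1.0 - 1e-8)
        wlog = float(r @ logp)
        alpha = min(max(-r.sum() / wlog if wlog < 0 else 1.0 - 1e-6, 1e-3), 1.0 - 1e-6)
        ll = float(np.sum(tot))
        if abs(ll - ll_old) < tol or (abs(q - q_old) < 1e-12 and abs(alpha - a_old) < 1e-12):
            return q, alpha, ll, it + 1
        delta = abs(ll - ll_old)
        ll_old = ll
        q_old, a_old = q, alpha
    # near-uniform inputs leave the likelihood flat along a (q, alpha)
    # ridge where the mixture is observationally uniform; residual creep
    # below 1e-4 per iteration is irrelevant on the chi-square LRT scale
    if delta < 1e-4:
        return q, alpha, ll_old, max_iter
    raise RuntimeError(
        f"marginal mixture EM did not converge (ll={ll_old:.6g}, delta={delta:.3g}, "
        f"q={q:.4g}, alpha={alpha:.4g})"
    )


def _joint_mixture_em(p1, p2, init, max_iter=5000, tol=1e-9):
    """Four-component EM over p-value pairs with free mixing proportions (log space)."""
    p1 = np.clip(p1, P_FLOOR, 1.0 - 1e-12)
    p2 = np.clip(p2, P_FLOOR, 1.0 - 1e-12)
    log1, log2 = np.log(p1), np.log(p2)
    pi, a1, a2 = np.array(init["pi"], dtype=float), init["alpha1"], init["alpha2"]
    ll_old = -np.inf
    for it in range(max_iter):
        lf1 = np.log(a1) + (a1 - 1.0) * log1
        lf2 = np.log(a2) + (a2 - 1.0) * log2
        zero = np.zeros_like(log1)
        ldens = np.column_stack([zero, lf1, lf2, lf1 + lf2])  # 00,10,01,11
        lnum = ldens + np.log(pi)[None, :]
        tot = special.logsumexp(lnum, axis=1)
        r = np.exp(lnum - tot[:, None])
        pi = np.clip(r.mean(axis=0), 1e-10, None)
        pi /= pi.sum()
        w1 = r[:, 1] + r[:, 3]
        w2 = r[:, 2] + r[:, 3]
        wl1 = float(w1 @ log1)
        wl2 = float(w2 @ log2)
        a1 = min(max(-w1.sum() / wl1 if wl1 < 0 else 1.0 - 1e-6, 1e-3), 1.0 - 1e-6)
        a2 = min(max(-w2.sum() / wl2 if wl2 < 0 else 1.0 - 1e-6, 1e-3), 1.0 - 1e-6)
        ll = float(np.sum(tot))
        if abs(ll - ll_old) < tol:
            return pi, a1, a2, ll, it + 1
        delta = abs(ll - ll_old)
        ll_old = ll
    if delta < 1e-4:
        return pi, a1, a2, ll_old, max_iter
    raise RuntimeError(
        f"joint mixture EM did not converge (ll={ll_old:.6g}, delta={delta:.3g}, pi={pi})"
    )


def overall_pleiotropy_lrt(p1_vec, p2_vec):
    """Likelihood-ratio test for overall pleiotropy between two traits.

    The gene p-value pairs are modelled as a four-component mixture over
    association states (null/alt per trait), null density uniform and
    alternative density ``alpha * p^(alpha-1)`` with 0 < alpha < 1.  Under
    independence of the two traits' association indicators the joint
    proportion factorizes, ``pi11 = (pi10+pi11)(pi01+pi11)``, and the
    constrained likelihood separates into two marginal two-component fits.
    The statistic ``2 * (ll_full - ll_constrained)`` is referred to the
    one-degree chi-square upper tail.

    Returns ``(lrt_stat, p_lrt, mixture_params)``.
    """
    p1 = np.asarray(p1_vec, dtype=float)
    p2 = np.asarray(p2_vec, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p vectors must be aligned")
    if p1.size < 500:
        raise ValueError("need at least 500 genes for the overall-pleiotropy LRT")

    q1, a1c, ll1, _ = _marginal_mixture_em(p1)
    q2, a2c, ll2, _ = _marginal_mixture_em(p2)
    ll_constrained = ll1 + ll2
    pi_init = np.array(
        [(1 - q1) * (1 - q2), q1 * (1 - q2), (1 - q1) * q2, q1 * q2]
    )
    pi, a1, a2, ll_full, n_iter = _joint_mixture_em(
        p1, p2, {"pi": pi_init, "alpha1": a1c, "alpha2": a2c}
    )
    lrt = max(0.0, 2.0 * (ll_full - ll_constrained))
    p_lrt = float(stats.chi2.sf(lrt, 1))
    params = {
        "pi": dict(zip(["pi00", "pi10", "pi01", "pi11"], pi)),
        "alpha1": a1,
        "alpha2": a2,
        "alpha1_constrained": a1c,
        "alpha2_constrained": a2c,
        "q1": q1,
        "q2": q2,
        "ll_full": ll_full,
        "ll_constrained": ll_constrained,
        "n_iter": n_iter,
    }
    return lrt, p_lrt, params


# ---------------------------------------------------------------------------
# pleiotropic-gene characterization

def effect_correlation(betas1, betas2) -> float:
    """Pearson correlation of per-SNP effect sizes across the two traits.

    Undefined (NaN) for genes with fewer than 3 SNPs or zero-variance
    effects.
    """
    b1 = np.asarray(betas1, dtype=float)
    b2 = np.asarray(betas2, dtype=float)
    if b1.size < 3 or b1.shape != b2.shape:
        return float("nan")
    if np.std(b1) == 0.0 or np.std(b2) == 0.0:
        return float("nan")
    return float(stats.pearsonr(b1, b2)[0])


def cochran_q(beta1, se1, beta2, se2):
    """Cochran's Q for heterogeneity of one SNP's effect across two traits.

    ``Q = (beta1 - beta2)^2 / (se1^2 + se2^2)``; p from the one-degree
    chi-square upper tail.  Vectorized over SNPs.
    """
    b1 = np.asarray(beta1, dtype=float)
    b2 = np.asarray(beta2, dtype=float)
    v = np.asarray(se1, dtype=float) ** 2 + np.asarray(se2, dtype=float) ** 2
    Q = (b1 - b2) ** 2 / v
    p = stats.chi2.sf(Q, 1)
    if Q.ndim == 0:
        return float(Q), float(p)
    return Q, p


def hypergeometric_enrichment(query_genes, gene_set, background):
    """Upper-tail hypergeometric over-representation test.

    ``P(X >= overlap)`` for ``X ~ Hypergeom(N=|background|,
    K=|gene_set & background|, n=|query & background|)``.
    """
    bg = set(background)
    query = set(query_genes) & bg
    geneset = set(gene_set) & bg
    overlap = len(query & geneset)
    p = float(stats.hypergeom.sf(overlap - 1, len(bg), len(geneset), len(query)))
    return overlap, min(p, 1.0)


# ---------------------------------------------------------------------------
# per-pair driver

@dataclass
class PleioPairResult:
    """Composite-null pleiotropy results for one trait pair."""

    trait_pair: tuple
    genes: pd.DataFrame  # gene_id, p1, p2, z1, z2, T, p_placo, q_fdr
    rho_z: float
    sigma1_sq: float
    sigma2_sq: float
    lrt_stat: float = float("nan")
    p_lrt: float = float("nan")

    @property
    def n_significant(self) -> int:
        return int((self.genes["q_fdr"] < 0.05).sum())

    def significant_genes(self, alpha: float = 0.05):
        return self.genes.loc[self.genes["q_fdr"] < alpha, "gene_id"].tolist()


def analyze_pair(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    trait_pair=("trait1", "trait2"),
    trim_p: float = 1e-4,
    run_lrt: bool = True,
) -> PleioPairResult:
    """Run the composite-null pleiotropy test for one pair of traits.

    Inputs are the per-trait gene association tables (``gene_id, p, z``).
    Genes are aligned on ``gene_id``; rho_z is estimated and removed; the
    sub-null variance parameters are the marginal variances of the
    de-correlated Z-scores; FDR is controlled per pair by BH.
    """
    merged = table1.merge(table2, on="gene_id", suffixes=("_1", "_2"))
    z1 = merged["z_1"].to_numpy()
    z2 = merged["z_2"].to_numpy()
    rho = estimate_z_correlation(z1, z2, trim_p=trim_p)
    z1s, z2s = decorrelate_z(z1, z2, rho)
    s1 = estimate_sigma_sq(z1s)
    s2 = estimate_sigma_sq(z2s)
    T, p = placo_test(z1s, z2s, s1, s2)
    q = fdr_bh(p)
    genes = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "p1": merged["p_1"],
            "p2": merged["p_2"],
            "z1": z1s,
            "z2": z2s,
            "T": T,
            "p_placo": p,
            "q_fdr": q,
        }
    )
    res = PleioPairResult(
        trait_pair=tuple(trait_pair),
        genes=genes,
        rho_z=rho,
        sigma1_sq=s1,
        sigma2_sq=s2,
    )
    if run_lrt and len(merged) >= 500:
        res.lrt_stat, res.p_lrt, _ = overall_pleiotropy_lrt(
            merged["p_1"].to_numpy(), merged["p_2"].to_numpy()
        )
    return res


def characterize_gene(gene_id, snp_ids, ss1, ss2, by_alpha: float = 0.05):
    """Effect-size correlation and SNP heterogeneity for one pleiotropic gene.

    Returns a dict with ``r_effect`` (NaN for genes with < 3 SNPs), the BY
    adjusted per-SNP heterogeneity q-values, and the proportion of SNPs
    with heterogeneous effects at ``q < by_alpha``.
    """
    s1 = ss1.set_index("snp_id").loc[snp_ids]
    s2 = ss2.set_index("snp_id").loc[snp_ids]
    r = effect_correlation(s1["beta"].to_numpy(), s2["beta"].to_numpy())
    Q, p_het = cochran_q(
        s1["beta"].to_numpy(), s1["se"].to_numpy(), s2["beta"].to_numpy(), s2["se"].to_numpy()
    )
    q_by = fdr_by(np.atleast_1d(p_het))
    return {
        "gene_id": gene_id,
        "n_snps": len(snp_ids),
        "r_effect": r,
        "Q": np.atleast_1d(Q),
        "p_het": np.atleast_1d(p_het),
        "q_by": q_by,
        "prop_heterogeneous": float(np.mean(q_by < by_alpha)),
    }


def shared_gene_summary(pair_results, alpha: float = 0.05):
    """Summaries of pleiotropic genes across trait pairs.

    Returns ``(pair_counts, gene_disorder_counts, sign_patterns)``:
    per-pair significant-gene counts, per-gene number of distinct traits it
    is linked to through any significant pair, and per gene/trait the sign
    of the (de-correlated) gene Z in the pairs where it was significant.
    """
    pair_rows = []
    gene_traits: dict = {}
    sign_rows = []
    for res in pair_results:
        t1, t2 = res.trait_pair
        sig = res.genes[res.genes["q_fdr"] < alpha]
        pair_rows.append({"trait1": t1, "trait2": t2, "n_significant": len(sig)})
        for _, row in sig.iterrows():
            gene_traits.setdefault(row["gene_id"], set()).update([t1, t2])
            sign_rows.append(
                {"gene_id": row["gene_id"], "trait": t1, "sign": int(np.sign(row["z1"]) or 1)}
            )
            sign_rows.append(
                {"gene_id": row["gene_id"], "trait": t2, "sign": int(np.sign(row["z2"]) or 1)}
            )
    pair_counts = pd.DataFrame(pair_rows, columns=["trait1", "trait2", "n_significant"])
    gene_counts = pd.DataFrame(
        [{"gene_id": g, "n_disorders": len(ts)} for g, ts in sorted(gene_traits.items())],
        columns=["gene_id", "n_disorders"],
    )
    if sign_rows:
        sign_patterns = (
            pd.DataFrame(sign_rows)
            .groupby(["gene_id", "trait"])["sign"]
            .agg(lambda s: int(np.sign(s.sum()) or 1))
            .unstack(fill_value=0)
        )
    else:
        sign_patterns = pd.DataFrame()
    return pair_counts, gene_counts, sign_patterns
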