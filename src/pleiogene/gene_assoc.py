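"""MAGMA-style gene-based association from SNP summary statistics.

A gene's statistic is the sum of its SNP chi-squares, ``S = sum_j z_j^2``.
Under the null the SNP Z-vector is multivariate normal with correlation
``R`` (the local LD matrix), so ``S`` is distributed as a weighted sum of
independent one-degree chi-squares with weights the eigenvalues of ``R``.
The tail probability is computed by numerical inversion of the
characteristic function (Imhof's integral) with a Satterthwaite
moment-matching fallback.

The gene p-value is turned into a signed normal score: the sign is that of
``sum_j beta_j * MAF_j`` over the gene's SNPs, and ``z = sign *
Phi^-1(1 - p/2)`` — the input the composite-null pleiotropy test consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "map_snps_to_genes",
    "weighted_chisq_sf",
    "gene_test_sum_chisq",
    "gene_sign",
    "gene_p_to_z",
    "gene_association_table",
]

P_FLOOR = 1e-300


def map_snps_to_genes(ss: pd.DataFrame, annot: pd.DataFrame) -> dict:
    """Assign SNPs to genes by position (1-based inclusive intervals).

    A SNP belongs to every gene whose ``[start, end]`` contains its
    position, so overlapping genes share SNPs.  Genes with no SNPs are
    omitted.  Returns ``{gene_id: list of snp_id}`` preserving genome order.
    """
    out = {}
    for chrom, genes in annot.groupby("chrom", sort=False):
        snps = ss[ss["chrom"].astype(str) == str(chrom)]
        if snps.empty:
            continue
        pos = snps["pos"].to_numpy()
        ids = snps["snp_id"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, ids = pos[order], ids[order]
        for _, g in genes.iterrows():
            lo = np.searchsorted(pos, g["start"], side="left")
            hi = np.searchsorted(pos, g["end"], side="right")
            if hi > lo:
                out[g["gene_id"]] = list(ids[lo:hi])
    return out


def _imhof_sf(s: float, lam: np.ndarray, abstol: float = 1e-12) -> float:
    """P(sum_i lam_i * chi2_1 >= s) by Imhof's characteristic-function inversion.

    The inversion integral ``1/2 + (1/pi) int_0^inf sin(theta(u)) /
    (u rho(u)) du`` is evaluated by a midpoint lattice sum.  The step is
    chosen so the aliasing images of the distribution fall many standard
    deviations beyond ``s`` (discretization error below the target
    tolerance); the sum is truncated once the non-oscillatory envelope
    ``1/(u rho(u))`` and its polynomial tail are below tolerance.
    """
    mu = float(np.sum(lam))
    sd = float(np.sqrt(2.0 * np.sum(lam**2)))
    # aliasing shift 4*pi/delta places spectral images ~40 sd past s
    delta = 4.0 * np.pi / (abs(s) + mu + 40.0 * sd)
    val = 0.0
    k0 = 0
    chunk = 8192
    max_terms = 1 << 21
    while True:
        u = (np.arange(k0, k0 + chunk) + 0.5) * delta
        lu = lam[:, None] * u[None, :]
        theta = 0.5 * np.sum(np.arctan(lu), axis=0) - 0.5 * s * u
        env = np.exp(-0.25 * np.sum(np.log1p(lu**2), axis=0)) / u
        val += float(np.sum(np.sin(theta) * env))
        k0 += chunk
        # truncation: integrating the oscillatory tail by parts bounds the
        # remainder by ~ (2/pi) * env(U) / s for the sin(s*u/2) oscillation
        if (2.0 / np.pi) * env[-1] / max(abs(s), 1.0) < 1e-10:
            break
        if k0 >= max_terms:
            raise FloatingPointError("Imhof lattice sum did not converge")
    p = 0.5 + val * delta / np.pi
    if not np.isfinite(p):
        raise FloatingPointError("Imhof integration failed")
    return p


def _satterthwaite_sf(s: float, lam: np.ndarray) -> float:
    """Moment-matched scaled chi-square tail, fallback when inversion fails."""
    c = np.sum(lam**2) / np.sum(lam)
    f = np.sum(lam) ** 2 / np.sum(lam**2)
    return float(stats.chi2.sf(s / c, f))


def weighted_chisq_sf(s: float, lam: np.ndarray, abstol: float = 1e-12) -> float:
    """Upper tail of a weighted sum of one-degree chi-squares.

    Eigenvalues below -1e-8 are rejected as non-PSD; small negative
    eigenvalues from roundoff are clipped at zero.  The result is clipped to
    ``(1e-300, 1]``; very small tails beyond the reach of the oscillatory
    integral fall back to the Satterthwaite approximation.
    """
    lam = np.asarray(lam, dtype=float)
    if lam.min() < -1e-8:
        raise ValueError("negative eigenvalues: LD matrix not PSD")
    lam = np.clip(lam, 0.0, None)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 1.0
    if s <= 0:
        return 1.0
    # exact reductions: a single weight, or all weights equal, is a scaled
    # chi-square
    if lam.size == 1 or np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        return float(min(max(stats.chi2.sf(s / lam[0], lam.size), P_FLOOR), 1.0))
    try:
        p = _imhof_sf(s, lam, abstol=abstol)
    except FloatingPointError:
        p = _satterthwaite_sf(s, lam)
    if p < 1e-10:
        # oscillatory quadrature loses relative accuracy in the far tail
        p = _satterthwaite_sf(s, lam)
    return float(min(max(p, P_FLOOR), 1.0))


def gene_test_sum_chisq(z_vec, R_sub) -> float:
    """Gene association p-value from SNP Z-scores and their LD submatrix.

    ``S = sum z_j^2`` referred to ``sum_i lambda_i chi2_1`` with lambda the
    eigenvalues of ``R_sub``.
    """
    z = np.asarray(z_vec, dtype=float)
    if z.ndim != 1 or z.size < 1:
        raise ValueError("z_vec must be a non-empty 1-D array")
    R = np.atleast_2d(np.asarray(R_sub, dtype=float))
    if R.shape != (z.size, z.size):
        raise ValueError("R_sub shape does not match z_vec")
    lam = np.linalg.eigvalsh(R)
    s = float(np.sum(z**2))
    return weighted_chisq_sf(s, lam)


def gene_sign(betas, mafs) -> int:
    """Gene effect direction: sign of ``sum beta_j * MAF_j`` (tie -> +1)."""
    betas = np.asarray(betas, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if betas.size == 0 or betas.shape != mafs.shape:
        raise ValueError("betas and mafs must be equal-length and non-empty")
    return 1 if float(np.sum(betas * mafs)) >= 0.0 else -1


def gene_p_to_z(p_gene: float, sign: int) -> float:
    """Signed normal score ``sign * Phi^-1(1 - p/2)``; p floored at 1e-300."""
    if not 0.0 < p_gene <= 1.0:
        raise ValueError("p_gene must lie in (0, 1]")
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    p = max(p_gene, P_FLOOR)
    return float(sign * stats.norm.isf(p / 2.0))


def gene_association_table(ss: pd.DataFrame, annot: pd.DataFrame, ld) -> pd.DataFrame:
    """Per-gene association table for one trait.

    Columns: ``gene_id, chrom, start, end, n_snps, S, p, sign, z``.  Genes
    without SNPs are omitted.
    """
    gene_snps = map_snps_to_genes(ss, annot)
    row_of = {sid: i for i, sid in enumerate(ss["snp_id"])}
    z_all = ss["z"].to_numpy()
    beta_all = ss["beta"].to_numpy()
    maf_all = ss["maf"].to_numpy()
    ginfo = annot.set_index("gene_id")
    rows = []
    for gene_id, snps in gene_snps.items():
        idx = [row_of[s] for s in snps]
        z = z_all[idx]
        R = ld.submatrix(snps)
        p = gene_test_sum_chisq(z, R)
        sgn = gene_sign(beta_all[idx], maf_all[idx])
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": ginfo.loc[gene_id, "chrom"],
                "start": ginfo.loc[gene_id, "start"],
                "end": ginfo.loc[gene_id, "end"],
                "n_snps": len(snps),
                "S": float(np.sum(z**2)),
                "p": p,
                "sign": sgn,
                "z": gene_p_to_z(p, sgn),
            }
        )
    return pd.DataFrame(rows)
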