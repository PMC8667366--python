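"""Synthetic GWAS summary statistics with block-LD structure and known truth.

The generator emulates the statistical structure that LD score regression,
the gene-based test, the composite-null pleiotropy test and two-sample MR
all assume about real summary data:

* block-diagonal LD with AR(1) correlation inside each block (always
  positive definite, closed-form entries, tunable decay);
* polygenic architecture simulated at the gene level: every SNP in a causal
  gene shares a gene effect plus SNP-level noise, so gene-level truth
  (causal / not causal, shared / trait-specific) is well defined;
* marginal GWAS Z-statistics drawn as multivariate normal with mean
  ``sqrt(N) * R @ b`` and covariance ``R`` per block (b = standardized joint
  effects), with cross-trait covariance ``overlap_rho * R`` reproducing the
  correlation of null Z-statistics induced by overlapping samples;
* an instrument-level MR dataset with a planted causal effect, optional
  balanced or directional horizontal pleiotropy, and invalid instruments.

All randomness flows from explicit integer seeds via
``numpy.random.default_rng``; the same seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LDReference",
    "ArchitectureSpec",
    "TruthRecord",
    "simulate_ld_reference",
    "default_gene_annotation",
    "simulate_summary_pair",
    "simulate_trait_set",
    "simulate_mr_dataset",
]

# non-palindromic allele pairs used for simulated variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


@dataclass
class LDReference:
    """Block-diagonal SNP correlation structure.

    Attributes
    ----------
    blocks : list of ndarray
        Square symmetric PSD correlation matrices, unit diagonal.
    snp_index : pandas.DataFrame
        One row per SNP in genome order: ``snp_id, chrom, pos, a1, a2, maf,
        block`` where ``block`` indexes into ``blocks``.
    n_ref : int
        Nominal reference-panel size (used for the bias-adjusted r^2 in LD
        score computation).
    """

    blocks: list
    snp_index: pd.DataFrame
    n_ref: int = 503
    _pos_in_block: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for b, mat in enumerate(self.blocks):
            if not np.allclose(np.diag(mat), 1.0):
                raise ValueError(f"block {b} diagonal is not 1")
            if np.abs(mat).max() > 1.0 + 1e-12:
                raise ValueError(f"block {b} has |r| > 1")
        self._pos_in_block = {
            sid: k
            for b, grp in self.snp_index.groupby("block", sort=True)
            for k, sid in enumerate(grp["snp_id"])
        }
        self._block_of = dict(zip(self.snp_index["snp_id"], self.snp_index["block"]))

    @property
    def n_snps(self) -> int:
        return len(self.snp_index)

    def block_of(self, snp_id: str) -> int:
        return self._block_of[snp_id]

    def submatrix(self, snp_ids) -> np.ndarray:
        """Correlation submatrix for a set of SNPs; zero across blocks."""
        snp_ids = list(snp_ids)
        m = len(snp_ids)
        out = np.zeros((m, m))
        for i, si in enumerate(snp_ids):
            bi, ki = self._block_of[si], self._pos_in_block[si]
            out[i, i] = 1.0
            for j in range(i + 1, m):
                sj = snp_ids[j]
                if self._block_of[sj] == bi:
                    out[i, j] = out[j, i] = self.blocks[bi][ki, self._pos_in_block[sj]]
        return out

    def r2(self, snp_a: str, snp_b: str) -> float:
        """Squared correlation between two SNPs (0 across blocks)."""
        if self._block_of[snp_a] != self._block_of[snp_b]:
            return 0.0
        b = self._block_of[snp_a]
        return float(self.blocks[b][self._pos_in_block[snp_a], self._pos_in_block[snp_b]] ** 2)


@dataclass
class ArchitectureSpec:
    """Simulation truth for a pair (or set) of traits.

    Parameters mirror the quantities the downstream estimators target:
    ``h2_true`` the SNP heritability per trait, ``n`` the GWAS sample sizes,
    ``prop_causal_genes`` the fraction of genes carrying nonzero effects,
    ``rg_true`` the genetic correlation between the two traits,
    ``overlap_rho`` the correlation of null Z-statistics induced by sample
    overlap (rho * Ns / sqrt(N1*N2)), and for MR ``beta_xy`` the causal
    exposure-to-outcome effect with ``pleiotropy_sd`` the spread of direct
    instrument-outcome effects.
    """

    h2_true: tuple = (0.3, 0.3)
    n: tuple = (50_000, 50_000)
    prop_causal_genes: float = 0.1
    rg_true: float = 0.0
    #: fraction of each trait's causal genes drawn from a common shared set
    #: (their effects correlated at rg_true); the remainder are
    #: trait-specific.  With 1.0 the genome-wide genetic correlation equals
    #: rg_true; below 1.0 it is diluted proportionally.
    prop_causal_shared: float = 1.0
    overlap_rho: float = 0.0
    beta_xy: float = 0.0
    pleiotropy_sd: float = 0.0
    #: fraction of effect variance shared by all SNPs in a causal gene;
    #: 0 keeps per-SNP effects independent, which matches the uncorrelated
    #: -effects assumption of LD score regression
    gene_effect_share: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for h2 in self.h2_true:
            if not 0.0 <= h2 < 1.0:
                raise ValueError("h2_true must lie in [0, 1)")
        if not -1.0 <= self.rg_true <= 1.0:
            raise ValueError("rg_true must lie in [-1, 1]")
        if not -1.0 <= self.overlap_rho <= 1.0:
            raise ValueError("overlap_rho must lie in [-1, 1]")
        if not 0.0 <= self.prop_causal_genes <= 1.0:
            raise ValueError("prop_causal_genes must lie in [0, 1]")
        # implied 2x2 genetic covariance must be PSD (always true for a
        # correlation in [-1, 1] with nonnegative h2); overlap matrix too.


@dataclass
class TruthRecord:
    """Ground truth emitted alongside simulated data."""

    causal_genes: pd.DataFrame  # gene_id + one boolean column per trait
    snp_effects: pd.DataFrame  # snp_id + one standardized-effect column per trait
    h2_true: tuple = ()
    rg_true: float = 0.0
    overlap_rho: float = 0.0
    beta_xy: float = 0.0

    def __post_init__(self):
        flag_cols = [c for c in self.causal_genes.columns if c != "gene_id"]
        for c in flag_cols:
            if self.causal_genes[c].dtype != bool:
                raise ValueError("causal flags must be boolean")


def simulate_ld_reference(
    n_blocks: int = 20,
    block_size: int = 50,
    rho_ar1: float = 0.6,
    maf_range: tuple = (0.05, 0.5),
    seed: int = 0,
    blocks_per_chrom: int = 20,
    snp_spacing_bp: int = 5_000,
    block_gap_bp: int = 100_000,
    n_ref: int = 503,
) -> LDReference:
    """Simulate a block-diagonal AR(1) LD reference.

    Each block is an AR(1) correlation matrix ``r_jk = rho**|j-k|``
    (positive definite for 0 <= rho < 1).  ``rho_ar1`` may be a scalar
    (every block identical) or a ``(low, high)`` range from which each
    block's decay is drawn uniformly — heterogeneous LD across loci, as in
    real genomes, which also spreads the LD score distribution.  SNPs are
    laid out on surrogate chromosomes, ``blocks_per_chrom`` blocks each,
    with uniform MAFs on ``maf_range`` and non-palindromic alleles.
    """
    rng = np.random.default_rng(seed)
    if np.ndim(rho_ar1) == 0:
        rhos = np.full(n_blocks, float(rho_ar1))
    else:
        lo, hi = rho_ar1
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("rho_ar1 range must satisfy 0 <= low <= high < 1")
        rhos = rng.uniform(lo, hi, size=n_blocks)
    if rhos.min() < 0.0 or rhos.max() >= 1.0:
        raise ValueError("rho_ar1 must lie in [0, 1)")
    idx = np.arange(block_size)
    dist = np.abs(idx[:, None] - idx[None, :])
    blocks = [rho**dist for rho in rhos]

    rows = []
    snp = 0
    for b in range(n_blocks):
        chrom = str(b // blocks_per_chrom + 1)
        block_in_chrom = b % blocks_per_chrom
        start = 1 + block_in_chrom * (block_size * snp_spacing_bp + block_gap_bp)
        mafs = rng.uniform(maf_range[0], maf_range[1], size=block_size)
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=block_size)
        for j in range(block_size):
            a1, a2 = _ALLELE_PAIRS[pair_idx[j]]
            rows.append(
                {
                    "snp_id": f"rs{snp + 1}",
                    "chrom": chrom,
                    "pos": start + j * snp_spacing_bp,
                    "a1": a1,
                    "a2": a2,
                    "maf": mafs[j],
                    "block": b,
                }
            )
            snp += 1
    snp_index = pd.DataFrame(rows)
    return LDReference(blocks=blocks, snp_index=snp_index, n_ref=n_ref)


def default_gene_annotation(ld: LDReference, snps_per_gene: int = 10) -> pd.DataFrame:
    """Tile each LD block with contiguous genes of ``snps_per_gene`` SNPs.

    Genes never straddle block boundaries, so a gene's LD submatrix is a
    dense AR(1) principal submatrix and gene-level truth is unambiguous.
    """
    rows = []
    g = 0
    for b, grp in ld.snp_index.groupby("block", sort=True):
        grp = grp.sort_values("pos")
        for lo in range(0, len(grp), snps_per_gene):
            sub = grp.iloc[lo : lo + snps_per_gene]
            rows.append(
                {
                    "gene_id": f"G{g + 1:05d}",
                    "chrom": sub["chrom"].iloc[0],
                    "start": int(sub["pos"].min()),
                    "end": int(sub["pos"].max()),
                }
            )
            g += 1
    return pd.DataFrame(rows)


def _gene_snp_slices(ld: LDReference, annot: pd.DataFrame):
    """Row indices of ld.snp_index for each gene (inclusive interval match)."""
    out = {}
    si = ld.snp_index
    for _, row in annot.iterrows():
        mask = (si["chrom"] == row["chrom"]) & (si["pos"] >= row["start"]) & (si["pos"] <= row["end"])
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx):
            out[row["gene_id"]] = idx
    return out


def _draw_gene_effects(ld, annot, h2_pair, prop_causal, rg, share, rng, prop_shared=1.0):
    """Standardized per-SNP effects for two traits with gene-level architecture.

    A causal gene's SNPs receive effects ``sqrt(share) * u_g +
    sqrt(1 - share) * v_j`` where the gene components (u_g1, u_g2) and the
    per-SNP components are bivariate normal with correlation ``rg``; with
    rg == 0 the two traits get independent causal gene sets.  Effects are
    rescaled so the summed squared standardized effect equals h2 exactly
    per trait.
    """
    m = ld.n_snps
    gene_idx = _gene_snp_slices(ld, annot)
    genes = list(gene_idx)
    n_causal = int(round(prop_causal * len(genes)))
    b = np.zeros((m, 2))
    flags = pd.DataFrame({"gene_id": genes})
    flags["trait1"] = False
    flags["trait2"] = False

    cov2 = np.array([[1.0, rg], [rg, 1.0]])
    L2 = np.linalg.cholesky(cov2 + 1e-12 * np.eye(2))

    if n_causal > 0:
        if rg != 0.0:
            n_shared = int(round(prop_shared * n_causal))
        else:
            n_shared = 0
        perm = rng.permutation(len(genes))
        shared = perm[:n_shared]
        free = perm[n_shared:]
        n_specific = n_causal - n_shared
        sets = {
            0: np.concatenate([shared, free[:n_specific]]),
            1: np.concatenate([shared, free[n_specific : 2 * n_specific]]),
        }
        shared_set = set(shared.tolist())
        shared_draw = {}
        for gi in set(np.concatenate([sets[0], sets[1]])):
            idx = gene_idx[genes[gi]]
            if gi in shared_set:
                u = L2 @ rng.standard_normal(2)
                v = rng.standard_normal((len(idx), 2)) @ L2.T
            else:
                u = rng.standard_normal(2)
                v = rng.standard_normal((len(idx), 2))
            eff = np.sqrt(share) * u[None, :] + np.sqrt(1.0 - share) * v
            shared_draw[gi] = (idx, eff)
        for t in (0, 1):
            col = f"trait{t + 1}"
            for gi in sets[t]:
                idx, eff = shared_draw[gi]
                b[idx, t] += eff[:, t]
                flags.loc[gi, col] = True
    for t in (0, 1):
        ss = float(np.sum(b[:, t] ** 2))
        if ss > 0:
            b[:, t] *= np.sqrt(h2_pair[t] / ss)
    return b, flags


def _draw_block_z(ld, mean1, mean2, overlap_rho, rng):
    """Per-block joint Z draw: cov R per trait, overlap_rho * R across traits."""
    z1 = np.empty(ld.n_snps)
    z2 = np.empty(ld.n_snps)
    C2 = np.linalg.cholesky(np.array([[1.0, overlap_rho], [overlap_rho, 1.0]]) + 1e-12 * np.eye(2))
    lo = 0
    for b, R in enumerate(ld.blocks):
        k = R.shape[0]
        L = np.linalg.cholesky(R + 1e-10 * np.eye(k))
        eps = L @ rng.standard_normal((k, 2)) @ C2.T
        z1[lo : lo + k] = mean1[lo : lo + k] + eps[:, 0]
        z2[lo : lo + k] = mean2[lo : lo + k] + eps[:, 1]
        lo += k
    return z1, z2


def _z_to_sumstats(ld: LDReference, z: np.ndarray, n: float) -> pd.DataFrame:
    si = ld.snp_index
    maf = si["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))
    beta = z * se
    return pd.DataFrame(
        {
            "snp_id": si["snp_id"],
            "chrom": si["chrom"],
            "pos": si["pos"],
            "a1": si["a1"],
            "a2": si["a2"],
            "maf": maf,
            "beta": beta,
            "se": se,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
            "n": float(n),
            "z": z,
        }
    )


def simulate_summary_pair(
    ld: LDReference,
    annot: pd.DataFrame,
    arch: ArchitectureSpec,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate marginal GWAS summary statistics for a pair of traits.

    Standardized joint effects ``b`` are drawn gene-wise (see
    :class:`ArchitectureSpec`); marginal Z-statistics per block follow
    ``MVN(sqrt(N_k) R b_k, R)`` with cross-trait covariance
    ``overlap_rho * R``; reported effects are ``beta = z * se`` with
    ``se = 1/sqrt(2 N maf (1 - maf))``.
    """
    rng = np.random.default_rng(arch.seed if seed is None else seed)
    b, flags = _draw_gene_effects(
        ld,
        annot,
        arch.h2_true,
        arch.prop_causal_genes,
        arch.rg_true,
        arch.gene_effect_share,
        rng,
        prop_shared=arch.prop_causal_shared,
    )
    mean = np.empty((ld.n_snps, 2))
    lo = 0
    for R in ld.blocks:
        k = R.shape[0]
        for t in (0, 1):
            mean[lo : lo + k, t] = np.sqrt(arch.n[t]) * (R @ b[lo : lo + k, t])
        lo += k
    z1, z2 = _draw_block_z(ld, mean[:, 0], mean[:, 1], arch.overlap_rho, rng)
    ss1 = _z_to_sumstats(ld, z1, arch.n[0])
    ss2 = _z_to_sumstats(ld, z2, arch.n[1])
    truth = TruthRecord(
        causal_genes=flags,
        snp_effects=pd.DataFrame(
            {"snp_id": ld.snp_index["snp_id"], "trait1": b[:, 0], "trait2": b[:, 1]}
        ),
        h2_true=arch.h2_true,
        rg_true=arch.rg_true,
        overlap_rho=arch.overlap_rho,
        beta_xy=arch.beta_xy,
    )
    return ss1, ss2, truth


def simulate_trait_set(
    ld: LDReference,
    annot: pd.DataFrame,
    n_traits: int,
    causal_effects: np.ndarray | None = None,
    h2: float = 0.3,
    n_gwas: float = 100_000,
    prop_causal_genes: float = 0.2,
    shared_frac: float = 0.0,
    shared_corr: float = 0.6,
    seed: int = 0,
) -> dict:
    """Simulate several traits with gene-level architectures and causal links.

    Each trait's causal genes split into a common pool shared by every
    trait (fraction ``shared_frac``), whose per-SNP effects are correlated
    at ``shared_corr`` across traits through an equicorrelated factor, and
    trait-specific genes with independent effects — planting both shared
    associated genes and nonzero genetic correlation
    (about ``shared_frac * shared_corr`` per pair).

    ``causal_effects[i, j]`` is the causal effect of trait i on trait j
    (acyclic in index order: only i < j entries are honoured); total
    standardized effects propagate along the causal graph, so instruments
    of an exposure show proportional outcome effects — the structure
    two-sample MR assumes.  GWAS noise is independent across traits (no
    sample overlap).

    Returns ``{"sumstats": {trait: DataFrame}, "effects": {trait: b},
    "causal_genes": DataFrame}``.
    """
    rng = np.random.default_rng(seed)
    m = ld.n_snps
    names = [f"T{i + 1}" for i in range(n_traits)]
    gene_idx = _gene_snp_slices(ld, annot)
    genes = list(gene_idx)
    G = len(genes)
    n_causal = int(round(prop_causal_genes * G))
    n_shared = int(round(shared_frac * n_causal))
    perm = rng.permutation(G)
    shared_pool = perm[:n_shared]
    free = perm[n_shared:]

    own = np.zeros((m, n_traits))
    flags = pd.DataFrame({"gene_id": genes})
    for t, name in enumerate(names):
        flags[name] = False
    for gi in shared_pool:
        idx = gene_idx[genes[gi]]
        common = rng.standard_normal(len(idx))
        for t in range(n_traits):
            own[idx, t] += np.sqrt(shared_corr) * common + np.sqrt(
                1.0 - shared_corr
            ) * rng.standard_normal(len(idx))
            flags.loc[gi, names[t]] = True
    n_specific = n_causal - n_shared
    for t in range(n_traits):
        if n_specific > 0:
            specific = rng.choice(free, size=n_specific, replace=False)
            for gi in specific:
                idx = gene_idx[genes[gi]]
                own[idx, t] += rng.standard_normal(len(idx))
                flags.loc[gi, names[t]] = True
    for t in range(n_traits):
        ss = float(np.sum(own[:, t] ** 2))
        if ss > 0:
            own[:, t] *= np.sqrt(h2 / ss)

    total = own.copy()
    if causal_effects is not None:
        for j in range(n_traits):
            for i in range(j):
                if causal_effects[i, j] != 0.0:
                    total[:, j] = total[:, j] + causal_effects[i, j] * total[:, i]
    sumstats = {}
    for t in range(n_traits):
        z = np.empty(m)
        lo = 0
        for R in ld.blocks:
            k = R.shape[0]
            L = np.linalg.cholesky(R + 1e-10 * np.eye(k))
            z[lo : lo + k] = np.sqrt(n_gwas) * (R @ total[lo : lo + k, t]) + L @ rng.standard_normal(k)
            lo += k
        sumstats[names[t]] = _z_to_sumstats(ld, z, n_gwas)
    return {
        "sumstats": sumstats,
        "effects": {names[t]: total[:, t] for t in range(n_traits)},
        "causal_genes": flags,
    }


def simulate_mr_dataset(
    n_instruments: int,
    arch: ArchitectureSpec,
    seed: int | None = None,
    sigma_x: float = 0.1,
    sx: float = 0.01,
    sy: float = 0.01,
    directional: float = 0.0,
    prop_invalid: float = 0.0,
    invalid_effect: float = 0.0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate an instrument-level two-sample MR dataset.

    True instrument-exposure effects have random sign and magnitude uniform
    on ``[0.5, 1.5] * sigma_x`` — bounded away from zero, as for real
    instruments, which are selected at a significance threshold and
    therefore exclude near-null effects.  Outcome effects are
    ``beta_xy * gamma + alpha_j + e`` where ``alpha_j ~
    N(directional, pleiotropy_sd^2)`` is horizontal pleiotropy (balanced
    when ``directional == 0``).  Direct effects are applied on the
    exposure-increasing-allele orientation (multiplied by ``sign(gamma)``),
    the scale on which directional pleiotropy is defined and on which the
    Egger intercept estimates it; the balanced case is unaffected.  A
    fraction ``prop_invalid`` of instruments additionally receives a fixed
    direct outcome effect ``invalid_effect``.  Estimated effects add normal
    noise at the stated SEs.
    """
    if n_instruments < 3:
        raise ValueError("need at least 3 instruments")
    rng = np.random.default_rng(arch.seed if seed is None else seed)
    gamma = rng.uniform(0.5 * sigma_x, 1.5 * sigma_x, size=n_instruments) * rng.choice(
        [-1.0, 1.0], size=n_instruments
    )
    alpha = rng.normal(directional, arch.pleiotropy_sd, size=n_instruments)
    invalid = np.zeros(n_instruments, dtype=bool)
    n_bad = int(round(prop_invalid * n_instruments))
    if n_bad:
        invalid[rng.choice(n_instruments, size=n_bad, replace=False)] = True
        alpha = alpha + invalid * invalid_effect
    orient = np.where(gamma >= 0, 1.0, -1.0)
    bx = gamma + rng.normal(0.0, sx, size=n_instruments)
    by = arch.beta_xy * gamma + orient * alpha + rng.normal(0.0, sy, size=n_instruments)
    maf = rng.uniform(0.05, 0.5, size=n_instruments)
    table = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(n_instruments)],
            "bx": bx,
            "sx": sx,
            "by": by,
            "sy": sy,
            "maf": maf,
            "invalid": invalid,
        }
    )
    truth = TruthRecord(
        causal_genes=pd.DataFrame({"gene_id": []}),
        snp_effects=pd.DataFrame(
            {"snp_id": table["snp_id"], "trait1": gamma, "trait2": arch.beta_xy * gamma + orient * alpha}
        ),
        h2_true=arch.h2_true,
        rg_true=arch.rg_true,
        beta_xy=arch.beta_xy,
    )
    return table, truth
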