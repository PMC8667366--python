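"""Two-sample Mendelian randomization from GWAS summary statistics.

Instruments are approximately independent SNPs associated with the
exposure (greedy LD clumping at a relaxed significance cutoff), optionally
screened against association with the outcome (Bonferroni within the
selected set) to limit horizontal pleiotropy.  Causal effects are estimated
by the inverse-variance-weighted (IVW) average of per-SNP ratio estimates,
the weighted median (robust to up to half the weight on invalid
instruments), and MR-Egger regression whose intercept indexes directional
pleiotropy.  :func:`mr_screen` runs a full exposure/outcome design with
joint FDR control and bidirectionality flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pleiogene.pleiotropy import fdr_bh

__all__ = [
    "MRResult",
    "enumerate_mr_design",
    "select_instruments",
    "filter_outcome_associated",
    "build_instrument_table",
    "ivw",
    "weighted_median",
    "mr_egger",
    "instrument_strength",
    "mr_screen",
]


@dataclass
class MRResult:
    """One exposure-outcome causal estimate for one estimator."""

    exposure: str = ""
    outcome: str = ""
    method: str = ""
    beta: float = float("nan")
    se: float = float("nan")
    p: float = float("nan")
    n_instruments: int = 0
    egger_intercept: float = float("nan")
    egger_intercept_p: float = float("nan")
    extras: dict = field(default_factory=dict)

    @property
    def ci95(self):
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    @property
    def or_point(self):
        return float(np.exp(self.beta))

    @property
    def or_ci(self):
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))


def enumerate_mr_design(childhood_traits, adulthood_traits) -> list:
    """Ordered (exposure, outcome) pairs for the bidirectional MR design.

    One-sided childhood-onset -> adulthood-onset relationships plus all
    ordered pairs among adulthood-onset traits; deduplicated, deterministic
    order.  Two childhood and ten adulthood traits give 2*10 + 10*9 = 110
    relationships.
    """
    childhood = list(dict.fromkeys(childhood_traits))
    adulthood = list(dict.fromkeys(adulthood_traits))
    design = []
    for c in childhood:
        for a in adulthood:
            if c != a:
                design.append((c, a))
    for a1 in adulthood:
        for a2 in adulthood:
            if a1 != a2:
                design.append((a1, a2))
    seen = set()
    out = []
    for pair in design:
        if pair not in seen:
            seen.add(pair)
            out.append(pair)
    return out


def select_instruments(
    exposure_ss: pd.DataFrame,
    ld,
    p_thresh: float = 1e-5,
    r2_thresh: float = 0.001,
    dist_bp: float = 10e6,
) -> list:
    """Greedy LD clumping of exposure-associated SNPs.

    Candidates with ``p < p_thresh`` are ranked by ascending p (ties broken
    by position then id); the top SNP is kept and remaining candidates on
    the same chromosome within ``dist_bp`` AND with ``r^2 > r2_thresh``
    against it are discarded; repeat until exhausted.  The result does not
    depend on the input row order.
    """
    cand = exposure_ss[exposure_ss["p"] < p_thresh]
    if cand.empty:
        warnings.warn("no candidate instruments below the significance cutoff")
        return []
    cand = cand.sort_values(["p", "chrom", "pos", "snp_id"], kind="stable")
    kept = []
    rows = cand[["snp_id", "chrom", "pos"]].to_numpy()
    active = np.ones(len(rows), dtype=bool)
    for i in range(len(rows)):
        if not active[i]:
            continue
        sid, chrom, pos = rows[i]
        kept.append(sid)
        for j in range(i + 1, len(rows)):
            if not active[j]:
                continue
            sid2, chrom2, pos2 = rows[j]
            if chrom2 != chrom or abs(pos2 - pos) > dist_bp:
                continue
            if ld.r2(sid, sid2) > r2_thresh:
                active[j] = False
    return kept


def filter_outcome_associated(instruments, outcome_ss: pd.DataFrame, alpha: float = 0.05) -> list:
    """Drop instruments associated with the outcome at Bonferroni-corrected p < alpha.

    The Bonferroni divisor is the number of selected instruments.
    """
    if not instruments:
        return []
    thresh = alpha / len(instruments)
    pmap = outcome_ss.set_index("snp_id")["p"]
    out = []
    for sid in instruments:
        p = pmap.get(sid, np.nan)
        if np.isnan(p) or p >= thresh:
            out.append(sid)
    return out


def build_instrument_table(instruments, exposure_ss, outcome_ss) -> pd.DataFrame:
    """Per-instrument effect table (bx, sx, by, sy, maf) on a common effect allele.

    Both summary-statistic frames must already be harmonized to the same
    reference panel, so alignment is by snp_id.
    """
    ex = exposure_ss.set_index("snp_id")
    ou = outcome_ss.set_index("snp_id")
    keep = [s for s in instruments if s in ex.index and s in ou.index]
    return pd.DataFrame(
        {
            "snp_id": keep,
            "bx": ex.loc[keep, "beta"].to_numpy(),
            "sx": ex.loc[keep, "se"].to_numpy(),
            "by": ou.loc[keep, "beta"].to_numpy(),
            "sy": ou.loc[keep, "se"].to_numpy(),
            "maf": ex.loc[keep, "maf"].to_numpy(),
        }
    )


def _drop_null_bx(table: pd.DataFrame) -> pd.DataFrame:
    bad = table["bx"] == 0.0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} instruments with bx = 0")
    return table[~bad]


def ivw(table: pd.DataFrame, allow_single: bool = False, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted causal estimate.

    Per-SNP ratio ``by/bx`` with weight ``bx^2 / sy^2``; multiplicative
    random-effects SE inflates the fixed-effect SE by
    ``sqrt(max(1, Q/(J-1)))``.
    """
    table = _drop_null_bx(table)
    J = len(table)
    if J == 0 or (J == 1 and not allow_single):
        raise ValueError("IVW requires at least 2 instruments")
    ratio = table["by"].to_numpy() / table["bx"].to_numpy()
    w = table["bx"].to_numpy() ** 2 / table["sy"].to_numpy() ** 2
    beta = float(np.sum(w * ratio) / np.sum(w))
    if J == 1:
        se = float(table["sy"].iloc[0] / abs(table["bx"].iloc[0]))
    else:
        Q = float(np.sum(w * (ratio - beta) ** 2))
        phi = max(1.0, Q / (J - 1)) if random_effects else 1.0
        se = float(np.sqrt(phi / np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return MRResult(method="ivw", beta=beta, se=se, p=p, n_instruments=J)


def weighted_median(table: pd.DataFrame, n_boot: int = 10_000, seed: int = 0) -> MRResult:
    """Weighted median of the per-SNP ratio estimates.

    Consistent when at least half the total weight comes from valid
    instruments.  SE by parametric bootstrap: instrument effects resampled
    at their SEs, the weighted median recomputed ``n_boot`` times.
    """
    table = _drop_null_bx(table)
    J = len(table)
    if J < 2:
        raise ValueError("weighted median requires at least 2 instruments")
    bx = table["bx"].to_numpy()
    sx = table["sx"].to_numpy()
    by = table["by"].to_numpy()
    sy = table["sy"].to_numpy()
    w = bx**2 / sy**2

    def wmedian(ratios, weights):
        order = np.argsort(ratios)
        r = ratios[order]
        cw = np.cumsum(weights[order])
        cw = (cw - 0.5 * weights[order]) / weights.sum()
        return float(np.interp(0.5, cw, r))

    beta = wmedian(by / bx, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(J)
        byb = by + sy * rng.standard_normal(J)
        ok = bxb != 0.0
        boots[b] = wmedian(byb[ok] / bxb[ok], bxb[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return MRResult(method="weighted_median", beta=beta, se=se, p=p, n_instruments=J)


def mr_egger(table: pd.DataFrame, min_instruments: int = 3) -> MRResult:
    """MR-Egger regression: WLS of by on bx with a free intercept.

    Instruments are oriented to non-negative exposure effects (flipping
    bx/by jointly); weights ``1/sy^2``; SEs carry a multiplicative
    overdispersion factor floored at 1.  The intercept estimates directional
    pleiotropy; its two-sided p-value uses the t distribution with J - 2
    degrees of freedom.
    """
    table = _drop_null_bx(table)
    J = len(table)
    if J < min_instruments:
        raise ValueError(f"MR-Egger requires at least {min_instruments} instruments")
    sign = np.sign(table["bx"].to_numpy())
    bx = table["bx"].to_numpy() * sign
    by = table["by"].to_numpy() * sign
    sy = table["sy"].to_numpy()
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(J), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    dof = J - 2
    phi = max(1.0, float(np.sum(w * resid**2) / dof)) if dof > 0 else 1.0
    cov = phi * np.linalg.inv(xtwx)
    icpt, slope = coef
    se_icpt, se_slope = np.sqrt(np.diag(cov))
    if dof > 0:
        p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, dof))
        p_icpt = float(2.0 * stats.t.sf(abs(icpt) / se_icpt, dof))
    else:
        p_slope = p_icpt = float("nan")
    return MRResult(
        method="egger",
        beta=float(slope),
        se=float(se_slope),
        p=p_slope,
        n_instruments=J,
        egger_intercept=float(icpt),
        egger_intercept_p=p_icpt,
        extras={"egger_intercept_se": float(se_icpt)},
    )


def instrument_strength(table: pd.DataFrame, n: float | None = None):
    """Instrument diagnostics: mean / min F and total variance explained.

    Per-SNP ``F_j = (bx_j / sx_j)^2`` and, on the standardized-trait scale,
    ``r2_j = 2 maf_j (1 - maf_j) bx_j^2``; ``total_r2`` is their sum.
    """
    bx = table["bx"].to_numpy()
    sx = table["sx"].to_numpy()
    maf = table["maf"].to_numpy()
    f = (bx / sx) ** 2
    r2 = 2.0 * maf * (1.0 - maf) * bx**2
    return float(f.mean()), float(f.min()), float(r2.sum())


def mr_screen(
    design,
    sumstats_by_trait: dict,
    ld,
    p_thresh: float = 1e-5,
    r2_thresh: float = 0.001,
    dist_bp: float = 10e6,
    outcome_alpha: float = 0.05,
    fdr_alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full MR design and assemble the results table.

    For every (exposure, outcome) relationship: clump instruments on the
    exposure, drop outcome-associated ones, then estimate with IVW,
    weighted median and Egger.  BH FDR is computed jointly over the IVW
    p-values of the whole design; bidirectional significance and sign
    patterns are flagged; the concordance (Pearson r) between weighted
    median and IVW estimates over significant associations is attached as
    ``DataFrame.attrs['wm_ivw_concordance']``.
    """
    if not design:
        return pd.DataFrame(
            columns=["exposure", "outcome", "n_instruments", "beta", "se", "p", "q_fdr"]
        )
    rows = []
    for k, (exposure, outcome) in enumerate(design):
        ss_x = sumstats_by_trait[exposure]
        ss_y = sumstats_by_trait[outcome]
        snps = select_instruments(ss_x, ld, p_thresh, r2_thresh, dist_bp)
        snps = filter_outcome_associated(snps, ss_y, outcome_alpha)
        table = build_instrument_table(snps, ss_x, ss_y)
        row = {
            "exposure": exposure,
            "outcome": outcome,
            "n_instruments": len(table),
        }
        if len(table) >= 2:
            fit = ivw(table)
            row.update(beta=fit.beta, se=fit.se, p=fit.p)
            wm = weighted_median(table, n_boot=n_boot, seed=seed + k)
            row.update(wm_beta=wm.beta, wm_se=wm.se, wm_p=wm.p)
            if len(table) >= 3:
                eg = mr_egger(table)
                row.update(
                    egger_beta=eg.beta,
                    egger_se=eg.se,
                    egger_p=eg.p,
                    egger_intercept=eg.egger_intercept,
                    egger_intercept_p=eg.egger_intercept_p,
                )
            mean_f, min_f, total_r2 = instrument_strength(table)
            row.update(mean_f=mean_f, min_f=min_f, total_r2=total_r2)
        else:
            row.update(beta=np.nan, se=np.nan, p=np.nan)
        rows.append(row)
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["q_fdr"] = np.nan
    if valid.any():
        out.loc[valid, "q_fdr"] = fdr_bh(out.loc[valid, "p"].to_numpy())
    out["significant"] = out["q_fdr"] < fdr_alpha
    sig_lookup = {
        (r.exposure, r.outcome): bool(r.significant) for r in out.itertuples()
    }
    out["bidirectional_significant"] = [
        bool(r.significant) and sig_lookup.get((r.outcome, r.exposure), False)
        for r in out.itertuples()
    ]
    out["or"] = np.exp(out["beta"])
    out["ci_low"] = out["beta"] - 1.96 * out["se"]
    out["ci_high"] = out["beta"] + 1.96 * out["se"]
    sig = out[out["significant"] & out["wm_beta"].notna()] if "wm_beta" in out else out.iloc[0:0]
    if len(sig) >= 3 and np.std(sig["beta"]) > 0 and np.std(sig["wm_beta"]) > 0:
        out.attrs["wm_ivw_concordance"] = float(
            np.corrcoef(sig["beta"], sig["wm_beta"])[0, 1]
        )
    else:
        out.attrs["wm_ivw_concordance"] = float("nan")
    return out
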