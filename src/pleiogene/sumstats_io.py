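"""Reading, validation, QC filtering and harmonization of GWAS summary statistics.

Summary statistics are carried as pandas DataFrames with the canonical
columns ``snp_id, chrom, pos, a1, a2, maf, beta, se, p, n, z`` (``a1`` is
the effect allele). :func:`read_summary_stats` maps arbitrary column layouts
onto this schema; :func:`apply_qc_filters` applies the standard five-stage
QC against an LD reference panel; :func:`harmonize_alleles` aligns every
trait to the panel's effect allele so that per-SNP effect directions are
comparable across traits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUMSTAT_COLUMNS",
    "QCReport",
    "read_summary_stats",
    "validate_summary_stats",
    "apply_qc_filters",
    "harmonize_alleles",
    "read_gene_annotation",
    "write_summary_stats",
    "write_table",
]

SUMSTAT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "a1",
    "a2",
    "maf",
    "beta",
    "se",
    "p",
    "n",
    "z",
]

#: default aliases recognized in raw summary-statistic headers
_DEFAULT_ALIASES = {
    "snp_id": ["snp", "snp_id", "rsid", "markername", "id"],
    "chrom": ["chr", "chrom", "chromosome"],
    "pos": ["bp", "pos", "position", "base_pair_location"],
    "a1": ["a1", "effect_allele", "allele1"],
    "a2": ["a2", "other_allele", "allele2"],
    "maf": ["frq", "maf", "freq", "eaf", "effect_allele_frequency"],
    "beta": ["beta", "b", "effect"],
    "or": ["or", "odds_ratio"],
    "se": ["se", "standard_error", "stderr"],
    "p": ["p", "pval", "p_value", "pvalue"],
    "n": ["n", "nobs", "sample_size"],
    "z": ["z", "zscore", "z_score"],
}

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_BASES = {"A", "C", "G", "T"}
_RS_PATTERN = re.compile(r"^rs\d+$")

#: MHC exclusion window on chromosome 6, base pairs, both ends inclusive
MHC_CHROM = "6"
MHC_START = 28_500_000
MHC_END = 33_500_000


@dataclass
class QCReport:
    """Per-stage SNP removal counts; each SNP is attributed to its first failing filter."""

    input: int = 0
    non_biallelic: int = 0
    strand_ambiguous: int = 0
    no_rsid: int = 0
    duplicated_or_unmatched: int = 0
    mhc_excluded: int = 0
    low_maf: int = 0
    retained: int = 0
    removal_order: tuple = (
        "non_biallelic",
        "strand_ambiguous",
        "no_rsid",
        "duplicated_or_unmatched",
        "mhc_excluded",
        "low_maf",
    )

    def removals(self) -> dict:
        return {k: getattr(self, k) for k in self.removal_order}

    def reconciles(self) -> bool:
        return self.retained == self.input - sum(self.removals().values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.input)]
        rows += list(self.removals().items())
        rows.append(("retained", self.retained))
        return pd.DataFrame(rows, columns=["stage", "count"])


def _resolve_columns(header, column_map):
    """Map raw header names onto canonical names, honouring user overrides."""
    lower = {str(h).lower(): h for h in header}
    resolved = {}
    overrides = dict(column_map or {})
    for canon, raw in overrides.items():
        if raw in header:
            resolved[canon] = raw
    for canon, aliases in _DEFAULT_ALIASES.items():
        if canon in resolved:
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    return resolved


def read_summary_stats(path, column_map=None, sep=None) -> pd.DataFrame:
    """Read delimited summary statistics into the canonical schema.

    Parameters
    ----------
    path : str or Path
        Whitespace- or tab-delimited text file with a header row.
    column_map : dict, optional
        Mapping from canonical column name (``beta``, ``p``, ...) to the raw
        column name in the file.  The special entry ``{"beta": "log(OR)"}``
        or mapping ``beta`` to an odds-ratio column detected via the ``or``
        aliases converts odds ratios to log-odds effects by natural log.
    sep : str, optional
        Field separator; default splits on arbitrary whitespace.

    Returns
    -------
    pandas.DataFrame
        Canonical columns; ``z`` derived as ``beta/se`` when absent and
        ``p`` derived from ``z`` by the two-sided normal tail when absent.
    """
    raw = pd.read_csv(path, sep=sep if sep is not None else r"\s+", dtype={"CHR": str})
    resolved = _resolve_columns(list(raw.columns), column_map)

    out = pd.DataFrame()
    or_col = resolved.pop("or", None)
    for canon, rawname in resolved.items():
        out[canon] = raw[rawname]
    if "beta" not in out.columns:
        if or_col is None:
            raise ValueError("summary statistics lack both BETA and OR columns")
        odds = pd.to_numeric(raw[or_col], errors="coerce")
        if (odds <= 0).any():
            raise ValueError("non-positive odds ratio cannot be log-transformed")
        out["beta"] = np.log(odds)

    for col in ("snp_id", "chrom", "a1", "a2"):
        if col not in out.columns:
            raise ValueError(f"missing mandatory column: {col}")
        out[col] = out[col].astype(str)
    out["a1"] = out["a1"].str.upper()
    out["a2"] = out["a2"].str.upper()

    for col in ("pos", "maf", "beta", "se", "p", "n", "z"):
        if col in out.columns:
            vals = pd.to_numeric(out[col], errors="coerce")
            if col in ("pos", "maf", "beta", "se", "n") and vals.isna().any():
                bad = out.index[vals.isna()][0]
                raise ValueError(f"non-numeric value in column {col!r} at row {bad}")
            out[col] = vals
    for col in ("pos", "maf", "beta", "se"):
        if col not in out.columns:
            raise ValueError(f"missing mandatory column: {col}")

    if (out["se"] <= 0).any():
        bad = out.index[out["se"] <= 0][0]
        raise ValueError(f"non-positive SE at row {bad} (snp {out.loc[bad, 'snp_id']})")

    if "z" not in out.columns:
        out["z"] = out["beta"] / out["se"]
    if "p" not in out.columns:
        out["p"] = 2.0 * stats.norm.sf(np.abs(out["z"]))
    if "n" not in out.columns:
        out["n"] = np.nan

    out["pos"] = out["pos"].astype(np.int64)
    return out[SUMSTAT_COLUMNS].reset_index(drop=True)


def validate_summary_stats(ss: pd.DataFrame, rtol: float = 1e-3) -> None:
    """Raise on schema or internal-consistency violations."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in ss.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if ss["snp_id"].duplicated().any():
        raise ValueError("duplicated snp_id")
    if (ss["maf"] <= 0).any():
        raise ValueError("non-positive MAF")
    if (ss["se"] <= 0).any():
        raise ValueError("non-positive SE")
    zb = ss["z"] * ss["se"]
    if not np.allclose(zb, ss["beta"], rtol=rtol, atol=1e-8):
        raise ValueError("z * se inconsistent with beta")


def _is_biallelic(a1, a2):
    return a1.isin(_BASES) & a2.isin(_BASES) & (a1 != a2)


def _is_ambiguous(a1, a2):
    pairs = list(zip(a1, a2))
    return pd.Series([p in _AMBIGUOUS_PAIRS for p in pairs], index=a1.index)


def apply_qc_filters(ss: pd.DataFrame, panel) -> tuple[pd.DataFrame, QCReport]:
    """Apply the five-stage QC against an LD reference panel.

    Stages, in order, each SNP counted at its first failure:

    i.   drop non-biallelic SNPs and strand-ambiguous (A/T, C/G) SNPs;
    ii.  drop SNPs whose identifier is not an rs label (``rs`` + digits);
    iii. drop duplicated SNPs (all copies) and SNPs absent from the panel or
         with alleles incompatible with the panel;
    iv.  drop SNPs inside the MHC region (chr6:28.5-33.5 Mb, inclusive);
    v.   keep SNPs with MAF > 0.01.

    Returns the filtered frame plus a :class:`QCReport`.  An empty result is
    allowed (reported, not raised).
    """
    report = QCReport(input=len(ss))
    df = ss.copy()

    bad_allele = ~_is_biallelic(df["a1"], df["a2"])
    report.non_biallelic = int(bad_allele.sum())
    df = df[~bad_allele]

    ambiguous = _is_ambiguous(df["a1"], df["a2"])
    report.strand_ambiguous = int(ambiguous.sum())
    df = df[~ambiguous]

    no_rs = ~df["snp_id"].str.match(_RS_PATTERN)
    report.no_rsid = int(no_rs.sum())
    df = df[~no_rs]

    dup = df["snp_id"].duplicated(keep=False)
    idx = panel.snp_index.set_index("snp_id")
    in_panel = df["snp_id"].isin(idx.index)
    compatible = pd.Series(False, index=df.index)
    hit = df[in_panel]
    if len(hit):
        pa1 = idx.loc[hit["snp_id"], "a1"].to_numpy()
        pa2 = idx.loc[hit["snp_id"], "a2"].to_numpy()
        same = (hit["a1"].to_numpy() == pa1) & (hit["a2"].to_numpy() == pa2)
        swap = (hit["a1"].to_numpy() == pa2) & (hit["a2"].to_numpy() == pa1)
        compatible.loc[hit.index] = same | swap
    unmatched = dup | ~compatible
    report.duplicated_or_unmatched = int(unmatched.sum())
    df = df[~unmatched]

    in_mhc = (df["chrom"].astype(str) == MHC_CHROM) & (df["pos"] >= MHC_START) & (df["pos"] <= MHC_END)
    report.mhc_excluded = int(in_mhc.sum())
    df = df[~in_mhc]

    low = ~(df["maf"] > 0.01)
    report.low_maf = int(low.sum())
    df = df[~low]

    report.retained = len(df)
    assert report.reconciles()
    return df.reset_index(drop=True), report


def harmonize_alleles(ss: pd.DataFrame, panel) -> pd.DataFrame:
    """Align effect alleles to the panel convention.

    SNPs whose (a1, a2) are swapped relative to the panel have beta and z
    negated and MAF re-folded; SNPs with alleles incompatible with the panel
    are dropped.  Applying the function twice equals applying it once.
    """
    idx = panel.snp_index.set_index("snp_id")
    df = ss[ss["snp_id"].isin(idx.index)].copy()
    pa1 = idx.loc[df["snp_id"], "a1"].to_numpy()
    pa2 = idx.loc[df["snp_id"], "a2"].to_numpy()
    same = (df["a1"].to_numpy() == pa1) & (df["a2"].to_numpy() == pa2)
    swap = (df["a1"].to_numpy() == pa2) & (df["a2"].to_numpy() == pa1)
    df = df[same | swap].copy()
    flip = swap[same | swap]
    df.loc[flip, "beta"] = -df.loc[flip, "beta"]
    df.loc[flip, "z"] = -df.loc[flip, "z"]
    maf = df.loc[flip, "maf"]
    df.loc[flip, "maf"] = np.minimum(1.0 - maf, np.maximum(maf, 1.0 - maf))
    # refold to (0, 0.5]
    df.loc[flip, "maf"] = np.where(df.loc[flip, "maf"] > 0.5, 1.0 - df.loc[flip, "maf"], df.loc[flip, "maf"])
    df.loc[flip, ["a1", "a2"]] = df.loc[flip, ["a2", "a1"]].to_numpy()
    return df.reset_index(drop=True)


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a BED-like gene annotation TSV (gene_id, chrom, start, end; 1-based inclusive)."""
    annot = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["gene_id", "chrom", "start", "end"]
    missing = [c for c in required if c not in annot.columns]
    if missing:
        raise ValueError(f"gene annotation missing columns: {missing}")
    if (annot["start"] > annot["end"]).any():
        raise ValueError("gene annotation with start > end")
    if annot.duplicated(["gene_id", "chrom"]).any():
        raise ValueError("duplicated gene_id within a chromosome")
    return annot[required].reset_index(drop=True)


def _format_float(x):
    if isinstance(x, float):
        return f"{x:.6g}"
    return x


def write_table(df: pd.DataFrame, path) -> None:
    """Write any pipeline table as TSV with floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_summary_stats(ss: pd.DataFrame, path) -> None:
    write_table(ss[SUMSTAT_COLUMNS], path)
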