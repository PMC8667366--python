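"""End-to-end orchestration: simulate -> QC -> gene tests -> pleiotropy ->
LDSC / clustering -> MR -> report, from a single declarative config.

Every output table is TSV; a manifest records the package version, the
config (including all seeds) and a content hash so that a rerun with the
same config is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pleiogene import genetic_corr, gene_assoc, mr, pleiotropy, sumstats_io, synthetic_data
from pleiogene._version import __version__ as _version

__all__ = ["RunConfig", "enumerate_trait_pairs", "run_pipeline", "PipelineError"]

logger = logging.getLogger("pleiogene")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage, original):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Declarative configuration for an end-to-end synthetic run."""

    n_traits: int = 3
    childhood_traits: list = field(default_factory=list)  # subset of trait names
    # LD reference
    n_blocks: int = 60
    block_size: int = 50
    rho_ar1: tuple = (0.2, 0.9)  # scalar or per-block uniform range
    snps_per_gene: int = 10
    # trait architecture
    h2: float = 0.3
    n_gwas: float = 100_000
    prop_causal_genes: float = 0.2
    shared_frac: float = 0.5
    shared_corr: float = 0.6
    causal_effects: list = field(default_factory=list)  # [[exposure, outcome, beta], ...]
    # thresholds
    fdr_alpha: float = 0.05
    instrument_p: float = 1e-5
    clump_r2: float = 0.001
    clump_dist: float = 10e6
    trim_p: float = 1e-4
    bonferroni_alpha: float = 0.05
    # reproducibility
    seed: int = 0
    out_dir: str = "pleiogene_run"

    def __post_init__(self):
        if not 0 < self.fdr_alpha < 1 or not 0 < self.bonferroni_alpha < 1:
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if not 0 < self.instrument_p < 1:
            raise ValueError("instrument_p must lie in (0, 1)")
        if self.clump_r2 < 0 or self.clump_dist <= 0:
            raise ValueError("invalid clumping thresholds")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def trait_names(self):
        return [f"T{i + 1}" for i in range(self.n_traits)]

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def enumerate_trait_pairs(traits) -> list:
    """All n*(n-1)/2 unordered trait pairs in deterministic order."""
    return list(combinations(list(traits), 2))


def _stage(name):
    def wrap(fn):
        def inner(state, config):
            t0 = time.monotonic()
            logger.info("stage %s: start", name)
            try:
                fn(state, config)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done in %.2fs", name, time.monotonic() - t0)

        inner.stage_name = name
        return inner

    return wrap


@_stage("simulate")
def _simulate(state, config: RunConfig):
    ld = synthetic_data.simulate_ld_reference(
        n_blocks=config.n_blocks,
        block_size=config.block_size,
        rho_ar1=config.rho_ar1,
        seed=config.seed,
    )
    annot = synthetic_data.default_gene_annotation(ld, snps_per_gene=config.snps_per_gene)
    names = config.trait_names()
    cmat = np.zeros((config.n_traits, config.n_traits))
    for exposure, outcome, beta in config.causal_effects:
        cmat[names.index(exposure), names.index(outcome)] = beta
    sim = synthetic_data.simulate_trait_set(
        ld,
        annot,
        config.n_traits,
        causal_effects=cmat,
        h2=config.h2,
        n_gwas=config.n_gwas,
        prop_causal_genes=config.prop_causal_genes,
        shared_frac=config.shared_frac,
        shared_corr=config.shared_corr,
        seed=config.seed + 1,
    )
    state["ld"] = ld
    state["annot"] = annot
    state["sumstats"] = sim["sumstats"]


@_stage("qc")
def _qc(state, config: RunConfig):
    ld = state["ld"]
    filtered = {}
    reports = []
    for trait, ss in state["sumstats"].items():
        out, report = sumstats_io.apply_qc_filters(ss, ld)
        out = sumstats_io.harmonize_alleles(out, ld)
        filtered[trait] = out
        frame = report.to_frame()
        frame.insert(0, "trait", trait)
        reports.append(frame)
    state["sumstats"] = filtered
    state["qc_report"] = pd.concat(reports, ignore_index=True)


@_stage("gene")
def _gene(state, config: RunConfig):
    state["gene_tables"] = {
        trait: gene_assoc.gene_association_table(ss, state["annot"], state["ld"])
        for trait, ss in state["sumstats"].items()
    }


@_stage("pleio")
def _pleio(state, config: RunConfig):
    results = []
    for t1, t2 in enumerate_trait_pairs(state["gene_tables"]):
        res = pleiotropy.analyze_pair(
            state["gene_tables"][t1],
            state["gene_tables"][t2],
            trait_pair=(t1, t2),
            trim_p=config.trim_p,
        )
        results.append(res)
    state["pair_results"] = results
    state["pleio_summary"] = pleiotropy.shared_gene_summary(results, alpha=config.fdr_alpha)


@_stage("ldsc")
def _ldsc(state, config: RunConfig):
    scores = genetic_corr.compute_ld_scores(state["ld"], n_ref=0)
    traits = list(state["sumstats"])
    h2_rows = []
    for trait in traits:
        fit = genetic_corr.ldsc_h2(state["sumstats"][trait], scores)
        h2_rows.append(
            {
                "trait": trait,
                "h2": fit.h2,
                "se_h2": fit.se_h2,
                "intercept": fit.intercept,
                "se_intercept": fit.se_intercept,
                "lambda_gc": fit.lambda_gc,
            }
        )
    rg_mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    rg_rows = []
    for t1, t2 in enumerate_trait_pairs(traits):
        fit = genetic_corr.ldsc_rg(state["sumstats"][t1], state["sumstats"][t2], scores)
        rg_mat.loc[t1, t2] = rg_mat.loc[t2, t1] = fit.rg
        rg_rows.append(
            {
                "trait1": t1,
                "trait2": t2,
                "rg": fit.rg,
                "se_rg": fit.se_rg,
                "gcov_intercept": fit.gcov_intercept,
            }
        )
    state["ldsc_h2"] = pd.DataFrame(h2_rows)
    state["ldsc_rg"] = pd.DataFrame(rg_rows)
    state["rg_matrix"] = rg_mat
    k = min(3, len(traits))
    cluster = genetic_corr.cluster_traits(rg_mat, k=k)
    state["clusters"] = cluster.labels.rename("cluster").rename_axis("trait").reset_index()


@_stage("mr")
def _mr(state, config: RunConfig):
    names = config.trait_names()
    childhood = [t for t in names if t in set(config.childhood_traits)]
    adulthood = [t for t in names if t not in set(config.childhood_traits)]
    design = mr.enumerate_mr_design(childhood, adulthood)
    state["mr_design"] = design
    state["mr_results"] = mr.mr_screen(
        design,
        state["sumstats"],
        state["ld"],
        p_thresh=config.instrument_p,
        r2_thresh=config.clump_r2,
        dist_bp=config.clump_dist,
        outcome_alpha=config.bonferroni_alpha,
        fdr_alpha=config.fdr_alpha,
        seed=config.seed + 2,
    )


@_stage("report")
def _report(state, config: RunConfig):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write = sumstats_io.write_table
    write(state["qc_report"], out / "qc_report.tsv")
    for trait, table in state["gene_tables"].items():
        write(table, out / f"gene_assoc_{trait}.tsv")
    pair_counts, gene_counts, sign_patterns = state["pleio_summary"]
    pair_level = pd.DataFrame(
        [
            {
                "trait1": r.trait_pair[0],
                "trait2": r.trait_pair[1],
                "rho_z": r.rho_z,
                "sigma1_sq": r.sigma1_sq,
                "sigma2_sq": r.sigma2_sq,
                "n_significant": int((r.genes["q_fdr"] < config.fdr_alpha).sum()),
                "lrt_stat": r.lrt_stat,
                "p_lrt": r.p_lrt,
            }
            for r in state["pair_results"]
        ]
    )
    for r in state["pair_results"]:
        write(r.genes, out / f"pleio_{r.trait_pair[0]}_{r.trait_pair[1]}.tsv")
    write(pair_level, out / "pleio_pairs.tsv")
    write(pair_counts, out / "pleio_pair_counts.tsv")
    write(gene_counts, out / "pleio_gene_counts.tsv")
    if len(sign_patterns):
        write(sign_patterns.reset_index(), out / "pleio_sign_patterns.tsv")
    write(state["ldsc_h2"], out / "ldsc_h2.tsv")
    write(state["ldsc_rg"], out / "ldsc_rg.tsv")
    write(state["clusters"], out / "cluster_labels.tsv")
    write(state["mr_results"].drop(columns=["significant", "bidirectional_significant"]).assign(
        significant=state["mr_results"]["significant"].astype(int),
        bidirectional=state["mr_results"]["bidirectional_significant"].astype(int),
    ), out / "mr_results.tsv")
    manifest = {
        "package": "pleiogene",
        "version": _version,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "n_snps": int(state["ld"].n_snps),
        "n_genes": int(len(state["annot"])),
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    state["manifest"] = manifest


_STAGES = [_simulate, _qc, _gene, _pleio, _ldsc, _mr, _report]


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute the pipeline; returns the in-memory state bundle.

    On stage failure a :class:`PipelineError` naming the stage is raised;
    outputs written by earlier stages are retained.
    """
    state: dict = {}
    selected = _STAGES if stages is None else [s for s in _STAGES if s.stage_name in stages]
    for stage in selected:
        stage(state, config)
    return state
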