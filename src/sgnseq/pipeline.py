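"""End-to-end orchestration: normalize, model, filter, classify, enrich, QC.

The pipeline mirrors the study's analysis order. TMM factors are computed
on all genes; the CPM > 1 expression gate (raw library sizes) defines the
differential-expression universe over all seven groups; voom weights and
the moderated group-means model are fit on the gated genes and all
pairwise contrasts extracted; the constant and dynamic specificity
filters combine those contrasts with TPM group means. Independently, the
CPM > 10 gate over SGN ages defines the dynamics universe, which is
re-modeled on SGN samples alone to call the four consecutive-age
transitions and assemble pattern categories, which are then scanned for
gene-group enrichment. A JSON manifest records every stage's gene counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .design import StudyDesign
from .io import (
    CountMatrix,
    read_counts,
    read_sample_sheet,
    read_lengths,
    read_gtf_lengths,
    read_gmt,
)
from .normalization import (
    NormFactors,
    tmm_factors,
    compute_cpm,
    compute_tpm,
    group_means,
)
from .diffexp import voom_transform, fit_model, ebayes_moderate, pairwise_contrasts, log_cpm
from .classify import (
    Thresholds,
    expression_gate,
    specificity_calls,
    call_transitions,
    assign_patterns,
    group_patterns,
    CONSTANT_SPECIFIC,
    DYNAMIC_SPECIFIC,
)
from .enrichment import GeneSetCollection, enrich_all_categories
from .qc import default_marker_panels, qc_report, sample_correlation

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File-level configuration of a pipeline run."""

    counts: str
    samples: str
    lengths: str | None = None
    gtf: str | None = None
    gmt: list[str] = field(default_factory=list)
    dialect: str = "plain"
    outdir: str = "sgnseq_out"
    seed: int = 0
    universe: str = "with-refs"  # or "sgn-only"
    run_specificity: bool = True
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory outputs of every stage."""

    norm_factors: NormFactors
    de_universe: list[str]
    dynamics_universe: list[str]
    contrasts: pd.DataFrame
    tpm_group_means: pd.DataFrame
    specificity: pd.DataFrame | None
    transitions: pd.DataFrame
    patterns: pd.DataFrame
    categories: dict[str, list[str]]
    category_summary: pd.DataFrame
    enrichment: dict[tuple[str, str], pd.DataFrame]
    qc_markers: pd.DataFrame | None
    sample_corr: pd.DataFrame
    manifest: dict


def _sgn_only(design: StudyDesign) -> StudyDesign:
    samples = tuple(s for s in design.samples if s[1] in design.sgn_age_order)
    return StudyDesign(tuple(design.sgn_age_order), samples, design.sgn_age_order)


def run_pipeline(
    m: CountMatrix,
    th: Thresholds | None = None,
    gene_sets: dict[str, dict[str, set[str]]] | None = None,
    run_specificity: bool = True,
    run_qc: bool = True,
) -> PipelineResult:
    """Run every analysis stage on an in-memory count matrix."""
    th = th or Thresholds()
    design = m.design
    if run_specificity and not design.has_references:
        raise ValueError(
            "specificity filters need HC and Glia groups; "
            "rerun with run_specificity=False or add references"
        )
    t0 = time.time()

    nf = tmm_factors(m)
    de_universe = expression_gate(m, th, "de_universe")
    logger.info("expression gate: %d of %d genes", len(de_universe), len(m.gene_ids))

    m_de = m.subset_genes(de_universe)
    nf_de = NormFactors(nf.factors, nf.lib_sizes)  # factors from all genes
    voomed = voom_transform(m_de, nf_de)
    fit = ebayes_moderate(fit_model(voomed))
    contrasts = pairwise_contrasts(fit)

    tpm = compute_tpm(m, m.lengths) if m.lengths is not None else None
    if tpm is not None:
        tpm_means = group_means(tpm, design)
    else:
        # no lengths: fall back to CPM means for reporting; specificity
        # genuinely needs TPM and is disabled upstream in that case
        tpm_means = group_means(compute_cpm(m), design)

    spec = None
    if run_specificity:
        if m.lengths is None:
            raise ValueError("specificity filters need gene lengths for TPM")
        spec = specificity_calls(contrasts, tpm_means.loc[de_universe], th, design)

    dyn_universe = expression_gate(m, th, "dynamics_universe")
    design_sgn = _sgn_only(design)
    m_dyn = CountMatrix(
        m.counts.loc[dyn_universe, design_sgn.sample_ids],
        design_sgn,
        m.lengths.loc[dyn_universe] if m.lengths is not None else None,
    )
    nf_sgn = NormFactors(
        nf.factors.loc[design_sgn.sample_ids], nf.lib_sizes.loc[design_sgn.sample_ids]
    )
    voomed_dyn = voom_transform(m_dyn, nf_sgn)
    fit_dyn = ebayes_moderate(fit_model(voomed_dyn))
    ages = list(design.sgn_age_order)
    trans_pairs = [(later, earlier) for earlier, later in zip(ages[:-1], ages[1:])]
    contrasts_dyn = pairwise_contrasts(fit_dyn, trans_pairs)
    cpm_norm = compute_cpm(m_dyn, nf_sgn)
    transitions = call_transitions(contrasts_dyn, cpm_norm, th, design_sgn)
    patterns = assign_patterns(transitions)
    categories, cat_summary = group_patterns(patterns, th)

    enrich: dict[tuple[str, str], pd.DataFrame] = {}
    if gene_sets:
        collections = {
            name: GeneSetCollection.from_gmt_sets(sets, dyn_universe)
            for name, sets in gene_sets.items()
        }
        enrich = enrich_all_categories(categories, collections)

    qc_tab = None
    corr = pd.DataFrame()
    if run_qc:
        expr_means = tpm_means if tpm is not None else group_means(compute_cpm(m), design)
        panels = [
            p
            for p in default_marker_panels()
            if p.gene_id in m.counts.index
            and p.expected_in in design.groups
            and all(g in design.groups for g in p.expected_absent)
        ]
        if panels:
            qc_tab = qc_report(expr_means, panels, "SGN_P8", th.qc_fold)
        corr, _ = sample_correlation(log_cpm(m, nf))

    n_const = int((spec["call"] == CONSTANT_SPECIFIC).sum()) if spec is not None else None
    n_dyn = int((spec["call"] == DYNAMIC_SPECIFIC).sum()) if spec is not None else None
    manifest = {
        "version": __version__,
        "n_genes": len(m.gene_ids),
        "n_samples": len(m.sample_ids),
        "de_universe": len(de_universe),
        "dynamics_universe": len(dyn_universe),
        "constant_specific": n_const,
        "dynamic_specific": n_dyn,
        "category_sizes": {c: len(g) for c, g in categories.items()},
        "qc_all_passed": bool(qc_tab["passed"].fillna(True).all()) if qc_tab is not None else None,
        "elapsed_s": round(time.time() - t0, 2),
    }
    assert sum(manifest["category_sizes"].values()) == len(dyn_universe)
    return PipelineResult(
        norm_factors=nf,
        de_universe=de_universe,
        dynamics_universe=dyn_universe,
        contrasts=contrasts,
        tpm_group_means=tpm_means,
        specificity=spec,
        transitions=transitions,
        patterns=patterns,
        categories=categories,
        category_summary=cat_summary,
        enrichment=enrich,
        qc_markers=qc_tab,
        sample_corr=corr,
        manifest=manifest,
    )


def write_outputs(res: PipelineResult, outdir: str | Path) -> None:
    """Write every stage table as TSV plus the JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample_id": res.norm_factors.factors.index,
            "tmm_factor": res.norm_factors.factors.to_numpy(),
            "lib_size": res.norm_factors.lib_sizes.to_numpy(),
            "effective_lib_size": res.norm_factors.effective_lib_sizes.to_numpy(),
        }
    ).to_csv(out / "norm_factors.tsv", sep="\t", index=False)
    pd.Series(res.de_universe, name="gene_id").to_csv(
        out / "de_universe.tsv", sep="\t", index=False
    )
    pd.Series(res.dynamics_universe, name="gene_id").to_csv(
        out / "dynamics_universe.tsv", sep="\t", index=False
    )
    res.contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False)
    res.tpm_group_means.to_csv(out / "tpm_group_means.tsv", sep="\t")
    if res.specificity is not None:
        res.specificity.to_csv(out / "specificity_calls.tsv", sep="\t")
    res.patterns.to_csv(out / "patterns.tsv", sep="\t")
    res.category_summary.to_csv(out / "category_summary.tsv", sep="\t", index=False)
    for (cat, ann), tab in res.enrichment.items():
        tab.to_csv(out / f"enrichment_{cat.replace('-', '_')}_{ann}.tsv", sep="\t", index=False)
    if res.qc_markers is not None:
        res.qc_markers.to_csv(out / "qc_markers.tsv", sep="\t", index=False)
    if not res.sample_corr.empty:
        res.sample_corr.to_csv(out / "sample_correlation.tsv", sep="\t")
    with open(out / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2)


def run_all(config: RunConfig) -> PipelineResult:
    """File-driven pipeline: read inputs per config, run, write outputs."""
    design = read_sample_sheet(config.samples)
    lengths = None
    if config.lengths:
        lengths = read_lengths(config.lengths)
    elif config.gtf:
        lengths = read_gtf_lengths(config.gtf)
    m = read_counts(config.counts, design, config.dialect, lengths)
    th = Thresholds(**config.thresholds)
    if config.run_specificity and not design.has_references:
        raise ValueError(
            "config requests specificity filters but HC/Glia groups are absent"
        )
    gene_sets = {Path(p).stem: read_gmt(p) for p in config.gmt} or None
    res = run_pipeline(
        m,
        th,
        gene_sets,
        run_specificity=config.run_specificity and config.universe == "with-refs",
    )
    res.manifest["config"] = asdict(config)
    write_outputs(res, config.outdir)
    return res
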