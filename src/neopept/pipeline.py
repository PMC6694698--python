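"""End-to-end orchestration: VCFs to the ranked long-peptide report.

Stages: merge the three caller VCFs into the high-confidence somatic call
set with phase-linked SNPs; map onto canonical transcripts and build mutant
contexts; enumerate and score class I/II candidates; apply the exclusion
filters and classify hotspot overlap; design, rank and select the top long
peptides; write the report and the customized proteome FASTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from neopept import annotate, binding, design, prioritize, variants
from neopept.config import ConfigurationError, PipelineConfig

log = logging.getLogger(__name__)


@dataclass
class Mutation:
    """One retained somatic mutation with everything the report needs."""

    variant: variants.ConsensusVariant
    effect: annotate.ProteinEffect
    transcript: annotate.TranscriptModel
    context: annotate.MutantContext
    candidates: list = field(default_factory=list)
    overlap: prioritize.HotspotOverlap | None = None
    expression_p90: float | None = None
    db_coverage: float = 0.0
    driver_status: str = ""
    filtered_by: str | None = None

    @property
    def mutation_id(self) -> str:
        return self.variant.variant_id

    @property
    def gene_symbol(self) -> str:
        return self.effect.gene_symbol

    @property
    def transcript_id(self) -> str:
        return self.effect.transcript_id

    def binders(self) -> list:
        return [c for c in self.candidates if c.is_predicted_binder]


@dataclass
class PipelineResult:
    consensus: list
    high_confidence: list
    mutations: list                 # retained Mutation objects
    excluded: list                  # filtered Mutation objects
    designs: list
    top: list
    report: pd.DataFrame
    counts: dict


def _load_models(cfg: PipelineConfig) -> list:
    if cfg.pwm_dir is None:
        raise ConfigurationError("pwm_dir not set and no external score table given")
    models = []
    alleles = [(a, "I") for a in cfg.alleles_i] + [(a, "II") for a in cfg.alleles_ii]
    for ai, (allele, cls) in enumerate(alleles):
        path = Path(cfg.pwm_dir) / f"{allele}.tsv"
        if not path.exists():
            raise ConfigurationError(f"no PWM file for allele {allele} at {path}")
        m = binding.PwmModel.from_tsv(path, allele, cls)
        lengths = cfg.hla_i_lengths if cls == "I" else cfg.hla_ii_lengths
        m.generate_decoys(np.random.default_rng([cfg.decoy_seed, ai]),
                          cfg.decoy_n, lengths)
        models.append(m)
    return models


def merge_variants(cfg: PipelineConfig) -> list:
    """Stage 1: union call set, origin, phase links, high-confidence set."""
    callsets = []
    for caller, path in (("gatk", cfg.vcf_gatk), ("mutect", cfg.vcf_mutect),
                         ("varscan", cfg.vcf_varscan)):
        if path is None:
            raise ConfigurationError(f"missing VCF path for caller {caller}")
        callsets.append(
            variants.parse_caller_vcf(path, caller, cfg.tumor_sample, cfg.germline_sample)
        )
    consensus = variants.merge_callsets(callsets)
    for v in consensus:
        variants.classify_origin(v)
    variants.link_phased_snps(consensus)
    return consensus


def build_mutations(cfg: PipelineConfig, high_confidence: list) -> list:
    """Stage 2: canonical-transcript effects and mutant contexts."""
    models = annotate.load_transcripts(cfg.gff3, cfg.genome_fasta, cfg.fasta_mode)
    canonical = annotate.canonical_transcripts(models)
    by_tid = {m.transcript_id: m for m in models}
    # linked germline effects are annotated on the partner's transcript
    mutations: list[Mutation] = []
    for v in high_confidence:
        if v.origin != variants.SOMATIC:
            continue
        hit = None
        for t in canonical.values():
            if t.chrom == v.chrom and t.cds_offset_of(v.pos - 1) is not None:
                hit = t
                break
        if hit is None:
            log.info("%s: outside any canonical CDS; ignored", v.variant_id)
            continue
        eff = annotate.annotate_effect(v, hit)
        if eff is None:
            continue
        if eff.consequence == annotate.MISSENSE:
            linked = [
                le
                for s in v.linked_snps
                if (le := annotate.annotate_effect(s, hit)) is not None
            ]
            ctx = annotate.build_snv_context(eff, hit, linked, cfg.context_flank)
        elif eff.consequence == annotate.FRAMESHIFT and cfg.indel_contexts:
            ctx = annotate.build_indel_context(eff, hit, cfg.indel_upstream)
        else:
            continue  # synonymous, stop-gained, disabled indels
        mutations.append(Mutation(variant=v, effect=eff, transcript=hit, context=ctx))
    return mutations


def predict_binders(cfg: PipelineConfig, mutations: list, ligand_db) -> None:
    """Stage 3: enumerate, score and call binders on every mutation."""
    models = None if cfg.external_scores_tsv else _load_models(cfg)
    for m in mutations:
        cands = binding.enumerate_candidates(
            m.context, "I", cfg.hla_i_lengths, cfg.include_linked_only_windows
        ) + binding.enumerate_candidates(
            m.context, "II", cfg.hla_ii_lengths, cfg.include_linked_only_windows
        )
        if cfg.external_scores_tsv:
            cands = binding.load_external_scores(cfg.external_scores_tsv, cands)
        else:
            cands = binding.score_candidates(cands, models)
        m.candidates = binding.call_binders(
            cands, ligand_db, cfg.rank_cutoff, cfg.rank_strict
        )


def apply_filters(cfg: PipelineConfig, mutations: list, ligand_db,
                  reference_proteins: dict) -> tuple[list, list]:
    """Stage 4: expression, wt-identity, hypermutated, underrepresented,
    hotspot overlap."""
    expression = pd.read_csv(cfg.expression_tsv, sep="\t")
    kept, dropped = prioritize.filter_expression(
        mutations, expression, cfg.tissue, cfg.expression_threshold,
        cfg.expression_percentile,
    )
    kept, d2 = prioritize.filter_hypermutated(kept, cfg.hypermutated_max)
    dropped += d2
    kept, d3 = prioritize.filter_underrepresented(
        kept, ligand_db, reference_proteins, cfg.coverage_threshold
    )
    dropped += d3
    blob = list(reference_proteins.values())
    for m in kept:
        m.candidates, removed = prioritize.filter_wt_identity(m.candidates, blob)
        if removed:
            log.info("%s: %d candidate(s) removed by wt-identity filter",
                     m.mutation_id, len(removed))
        m.overlap = prioritize.classify_ipmsdb_overlap(
            m.context, m.candidates, ligand_db, m.transcript_id,
            reference_proteins.get(m.transcript_id, ""), cfg.min_partial_overlap,
        )
    return kept, dropped


def design_and_rank(cfg: PipelineConfig, mutations: list, drivers: dict) -> tuple:
    """Stage 5: one design per mutation, ranked; top N selected."""
    designs = []
    for m in mutations:
        d = design.design_long_peptide(m.context, m.binders(),
                                       cfg.rank_cutoff, cfg.rank_strict)
        if d is None:
            log.info("%s: no predicted binders; excluded from ranking", m.mutation_id)
            continue
        d.chrom = m.variant.chrom
        d.pos = m.variant.pos
        d.gene_symbol = m.gene_symbol
        d.mutation_label = m.effect.hgvs_label
        d.expression_p90 = m.expression_p90
        d.driver_status = drivers.get(m.gene_symbol, "")
        if m.overlap is not None:
            d.ipmsdb_i = m.overlap.class_i
            d.ipmsdb_ii = m.overlap.class_ii
        designs.append(d)
    ranked = design.rank_designs(designs)
    top = design.select_top(ranked, cfg.top_n)
    return ranked, top


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage; optionally write the output tables under *outdir*."""
    consensus = merge_variants(cfg)
    high_conf = variants.select_high_confidence(consensus)
    mutations = build_mutations(cfg, high_conf)
    ligand_db = (
        prioritize.LigandDatabase.from_tsv(cfg.ligand_db_tsv)
        if cfg.ligand_db_tsv
        else None
    )
    predict_binders(cfg, mutations, ligand_db)
    tmodels = annotate.load_transcripts(cfg.gff3, cfg.genome_fasta, cfg.fasta_mode)
    reference_proteins = {t.transcript_id: t.protein_sequence for t in tmodels}
    if ligand_db is None:
        ligand_db = prioritize.LigandDatabase(
            pd.DataFrame(columns=["peptide", "hla_class", "protein", "n_observations"])
        )
    retained, excluded = apply_filters(cfg, mutations, ligand_db, reference_proteins)
    drivers = {}
    if cfg.driver_tsv:
        ddf = pd.read_csv(cfg.driver_tsv, sep="\t")
        drivers = dict(zip(ddf["gene"], ddf["status"]))
    ranked, top = design_and_rank(cfg, retained, drivers)
    report = design.build_report(top)
    counts = {
        "consensus_variants": len(consensus),
        "high_confidence": len(high_conf),
        "somatic_contexts": len(mutations),
        "retained_after_filters": len(retained),
        "designs": len(ranked),
        "reported": len(top),
    }
    for stage, n in counts.items():
        log.info("%s: %d", stage, n)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        variants.write_variant_table(consensus, outdir / "variants.tsv")
        design.write_report(report, outdir / "report.tsv")
        effects_by_tid: dict[str, list] = {}
        for m in mutations:
            effects_by_tid.setdefault(m.transcript_id, []).append(m.effect)
            for s in m.variant.linked_snps:
                le = annotate.annotate_effect(s, m.transcript)
                if le is not None and le.consequence == annotate.MISSENSE:
                    effects_by_tid[m.transcript_id].append(le)
        annotate.build_custom_proteome(tmodels, effects_by_tid,
                                       outdir / "custom_proteome.fasta")
    return PipelineResult(
        consensus=consensus,
        high_confidence=high_conf,
        mutations=retained,
        excluded=excluded,
        designs=ranked,
        top=top,
        report=report,
        counts=counts,
    )
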