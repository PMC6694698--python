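"""Pipeline configuration.

All tunable thresholds live here with their defaults; a YAML file with the
same key names can override any subset.  Coordinates are 0-based half-open
internally; all file I/O is 1-based (VCF/GFF3 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigurationError(Exception):
    """Raised when inputs or settings are inconsistent with the pipeline contract."""


@dataclass
class PipelineConfig:
    """Thresholds, seeds and input paths for a full pipeline run.

    Defaults follow the published procedure: percentile-rank binder cutoff of
    5 (strict ``<``), expression exclusion below 1 TPM (90th percentile),
    frameshift-indel contexts disabled, top 10 long peptides reported.
    """

    # sample columns in the VCFs
    tumor_sample: str = "TUMOR"
    germline_sample: str = "NORMAL"

    # binder calling
    rank_cutoff: float = 5.0
    rank_strict: bool = True          # strict "<" (config switch for "<=")
    hla_i_lengths: tuple = (9, 10, 11, 12)
    hla_ii_lengths: tuple = (12, 13, 14, 15, 16, 17, 18, 19)
    include_linked_only_windows: bool = False

    # decoy calibration for the built-in PWM scorer
    decoy_n: int = 100_000
    decoy_seed: int = 42

    # context construction
    context_flank: int = 15           # residues either side of the mutation
    indel_contexts: bool = False      # frameshift ORF contexts (off by default)
    indel_upstream: int = 24          # unaltered residues ahead of the novel ORF

    # exclusion filters
    expression_threshold: float = 1.0     # TPM; strict "<" drops
    expression_percentile: float = 90.0
    hypermutated_max: int = 3             # genes with more somatic SNVs dropped
    coverage_threshold: float = 0.0       # ligand-DB representation; 0 = inert
    min_partial_overlap: int = 5          # residues for PARTIAL hotspot overlap

    # report
    top_n: int = 10
    tissue: str = "pancreas"

    # inputs (filled from YAML for run-all)
    vcf_gatk: str | None = None
    vcf_mutect: str | None = None
    vcf_varscan: str | None = None
    gff3: str | None = None
    genome_fasta: str | None = None
    fasta_mode: str = "genome"        # "genome" or "cds"
    expression_tsv: str | None = None
    ligand_db_tsv: str | None = None
    pwm_dir: str | None = None
    external_scores_tsv: str | None = None
    driver_tsv: str | None = None
    observed_peptides_tsv: str | None = None
    alleles_i: list = field(default_factory=lambda: ["A0101", "A0201"])
    alleles_ii: list = field(default_factory=lambda: ["DRB10101"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("hla_i_lengths", "hla_ii_lengths"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def resolve(self, base: str | Path) -> "PipelineConfig":
        """Return a copy with relative input paths resolved against *base*."""
        base = Path(base)
        out = PipelineConfig(**{f.name: getattr(self, f.name) for f in fields(self)})
        for key in (
            "vcf_gatk", "vcf_mutect", "vcf_varscan", "gff3", "genome_fasta",
            "expression_tsv", "ligand_db_tsv", "pwm_dir", "external_scores_tsv",
            "driver_tsv", "observed_peptides_tsv",
        ):
            val = getattr(out, key)
            if val is not None and not Path(val).is_absolute():
                setattr(out, key, str(base / val))
        return out
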