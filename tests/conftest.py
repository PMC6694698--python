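"""Shared fixtures: a seeded synthetic bundle, one full pipeline run, and
small builders for VCFs and transcript models."""

from __future__ import annotations

import pytest

from neopept import pipeline
from neopept.annotate import TranscriptModel, _translate
from neopept.config import PipelineConfig
from neopept.fixtures import FixtureSpec, expected_truth, generate_cohort

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=1,length=1000000>\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL\n"
)

# one codon per amino acid, for deterministic toy CDS construction
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAA", "R": "CGT", "S": "AGT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def encode_protein(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


def make_transcript(
    protein: str | None = None,
    cds: str | None = None,
    transcript_id: str = "TR1",
    gene_symbol: str = "GENE1",
    chrom: str = "1",
    strand: str = "+",
    start0: int = 100,
) -> TranscriptModel:
    """Single-exon transcript model straight from a protein or CDS string."""
    if cds is None:
        cds = encode_protein(protein)
    prot = _translate(cds)
    if prot.endswith("*"):
        prot = prot[:-1]
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_symbol=gene_symbol,
        chrom=chrom,
        strand=strand,
        exons=[(start0, start0 + len(cds))],
        cds=[(start0, start0 + len(cds))],
        cds_sequence=cds,
        protein_sequence=prot,
    )


@pytest.fixture
def write_vcf(tmp_path):
    def _write(name: str, rows: list[str]) -> str:
        path = tmp_path / name
        path.write_text(VCF_HEADER + "".join(r.rstrip("\n") + "\n" for r in rows))
        return str(path)

    return _write


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    return generate_cohort(FixtureSpec(seed=1), tmp_path_factory.mktemp("fx"))


@pytest.fixture(scope="session")
def truth(bundle):
    return expected_truth(bundle)


@pytest.fixture(scope="session")
def bundle_config(bundle) -> PipelineConfig:
    return PipelineConfig.from_yaml(bundle.paths["config"]).resolve(bundle.root)


@pytest.fixture(scope="session")
def result(bundle_config):
    return pipeline.run_pipeline(bundle_config)
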