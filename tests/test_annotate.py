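"""Transcript loading, effect annotation, mutant contexts, the customized
proteome and MS-peptide flagging."""

import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import encode_protein, make_transcript
from neopept.annotate import (
    FRAMESHIFT,
    MISSENSE,
    SYNONYMOUS,
    annotate_effect,
    build_custom_proteome,
    build_indel_context,
    build_snv_context,
    canonical_transcripts,
    flag_observed_mutant_peptides,
    load_transcripts,
)
from neopept.variants import ConsensusVariant


def variant(pos, ref, alt, chrom="1"):
    return ConsensusVariant(chrom, pos, ref, alt, frozenset({"mutect"}), True, False)


def write_toy_genome(tmp_path, cds, strand="+", start0=10):
    """Single gene at *start0* on chromosome 1; returns (gff3, fasta) paths."""
    pad = "A" * start0
    chrom_seq = pad + (cds if strand == "+" else str(Seq(cds).reverse_complement())) + "A" * 5
    fasta = tmp_path / "g.fa"
    fasta.write_text(">1\n" + chrom_seq + "\n")
    start, end = start0 + 1, start0 + len(cds)
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        f"1\ttest\tgene\t{start}\t{end}\t.\t{strand}\t.\tID=G1;Name=G1\n"
        f"1\ttest\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID=T1;Parent=G1;gene_name=G1\n"
        f"1\ttest\texon\t{start}\t{end}\t.\t{strand}\t.\tID=T1.e;Parent=T1\n"
        f"1\ttest\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID=T1.c;Parent=T1\n"
    )
    return gff, fasta


def test_load_single_exon_plus_strand(tmp_path):
    gff, fasta = write_toy_genome(tmp_path, "ATGGCTTGA")
    (t,) = load_transcripts(gff, fasta)
    assert t.protein_sequence == "MA"
    assert t.gene_symbol == "G1" and t.strand == "+"


def test_load_minus_strand_reverse_complemented(tmp_path):
    gff, fasta = write_toy_genome(tmp_path, "ATGGCTAAATGA", strand="-")
    (t,) = load_transcripts(gff, fasta)
    assert t.protein_sequence == "MAK"


def test_incomplete_cds_flagged_and_excluded(tmp_path):
    gff, fasta = write_toy_genome(tmp_path, "ATGGCTTG")  # length 8
    (t,) = load_transcripts(gff, fasta)
    assert t.incomplete and t.protein_sequence == ""


def test_canonical_transcript_longest_cds():
    a = make_transcript(protein="MAAAA", transcript_id="TRB", gene_symbol="G")
    b = make_transcript(protein="MAAAAAAA", transcript_id="TRZ", gene_symbol="G")
    c = make_transcript(protein="MAAAAAAA", transcript_id="TRA", gene_symbol="G")
    assert canonical_transcripts([a, b, c])["G"].transcript_id == "TRA"  # tie: lexicographic


# ---------------------------------------------------------------------------
# effects


def test_missense_codon_change():
    # codon 2 GCT -> GTT: p.Ala2Val
    t = make_transcript(cds="ATGGCTAAATAA", start0=0)
    e = annotate_effect(variant(5, "C", "T"), t)
    assert e.consequence == MISSENSE
    assert (e.aa_pos, e.wt_aa, e.mut_aa) == (2, "A", "V")
    assert e.hgvs_label == "p.Ala2Val"


def test_synonymous_codon_change():
    # codon 2 GCT -> GCC
    t = make_transcript(cds="ATGGCTAAATAA", start0=0)
    e = annotate_effect(variant(6, "T", "C"), t)
    assert e.consequence == SYNONYMOUS


def test_minus_strand_effect_uses_complement():
    cds = "ATGGCTAAATAA"
    t = make_transcript(cds=cds, strand="-", start0=0)
    # genomic sequence is revcomp(cds), length 12; CDS base at offset 4 ("C")
    # sits at genomic pos0 = 12-1-4 = 7, genomic ref = complement = "G"
    e = annotate_effect(variant(8, "G", "A"), t)
    assert e.consequence == MISSENSE and e.hgvs_label == "p.Ala2Val"


def test_insertion_is_frameshift():
    t = make_transcript(protein="MKTAYIAKQR", start0=0)
    pos = 3 * 4 + 1  # first base of codon 5
    e = annotate_effect(variant(pos, "A", "AT"), t)
    assert e.consequence == FRAMESHIFT
    assert e.aa_pos == 5 and e.hgvs_label.endswith("fs")


def test_variant_outside_cds_ignored():
    t = make_transcript(protein="MKT", start0=100)
    assert annotate_effect(variant(5, "A", "T"), t) is None


# ---------------------------------------------------------------------------
# SNV contexts


def _interior_protein(n=300, seed=3):
    rng = np.random.default_rng(seed)
    return "M" + "".join(np.array(list("ACDEFGHIKLNPQRSTVWY"))[rng.integers(0, 19, n - 1)])


def test_interior_missense_centered_31mer():
    prot = _interior_protein()
    t = make_transcript(protein=prot, start0=0)
    from neopept.annotate import ProteinEffect

    e = ProteinEffect("TR1", "GENE1", 100, prot[99], "W" if prot[99] != "W" else "Y",
                      "p.X100X", MISSENSE, variant(1, "A", "T"))
    ctx = build_snv_context(e, t)
    assert len(ctx.mutant_sequence) == 31
    assert ctx.mutated_index == 16
    assert ctx.mutant_sequence[15] == e.mut_aa
    assert ctx.wt_sequence == prot[84:115]


def test_left_truncated_context():
    prot = _interior_protein(60)
    t = make_transcript(protein=prot, start0=0)
    from neopept.annotate import ProteinEffect

    e = ProteinEffect("TR1", "GENE1", 5, prot[4], "K" if prot[4] != "K" else "R",
                      "p.X5X", MISSENSE, variant(1, "A", "T"))
    ctx = build_snv_context(e, t)
    assert ctx.wt_sequence == prot[:20]
    assert len(ctx) == 20 and ctx.mutated_index == 5


def test_linked_edit_applied_inside_window():
    prot = _interior_protein()
    t = make_transcript(protein=prot, start0=0)
    from neopept.annotate import ProteinEffect

    main = ProteinEffect("TR1", "GENE1", 100, prot[99], "W", "p.X100W", MISSENSE,
                         variant(1, "A", "T"))
    linked_in = ProteinEffect("TR1", "GENE1", 92, prot[91], "H", "p.X92H", MISSENSE,
                              variant(2, "C", "G"))
    linked_out = ProteinEffect("TR1", "GENE1", 200, prot[199], "H", "p.X200H", MISSENSE,
                               variant(3, "C", "G"))
    ctx = build_snv_context(main, t, [linked_in, linked_out])
    assert ctx.applied_linked_edits == [(8, prot[91], "H")]
    assert ctx.mutant_sequence[7] == "H"
    # wt sequence keeps reference residues everywhere
    assert ctx.wt_sequence == prot[84:115]
    diffs = [i for i, (a, b) in enumerate(zip(ctx.wt_sequence, ctx.mutant_sequence)) if a != b]
    assert diffs == [7, 15]


def test_context_matches_translated_edited_cds():
    """Brute-force oracle: translating the edited CDS reproduces the context."""
    rng = np.random.default_rng(11)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(25):
        prot = "M" + "".join(aas[rng.integers(0, 20, 80)])
        cds = encode_protein(prot)
        t = make_transcript(cds=cds, start0=0)
        ci = int(rng.integers(1, 80))
        codon = cds[3 * ci : 3 * ci + 3]
        cp = int(rng.integers(3))
        base = "ACGT"[rng.integers(4)]
        if base == codon[cp]:
            continue
        mut_codon = codon[:cp] + base + codon[cp + 1 :]
        mut_aa = str(Seq(mut_codon).translate())
        if mut_aa in ("*", prot[ci]):
            continue
        v = variant(3 * ci + cp + 1, codon[cp], base)
        e = annotate_effect(v, t)
        ctx = build_snv_context(e, t)
        # oracle: independent translation of the edited CDS window
        edited = cds[: 3 * ci] + mut_codon + cds[3 * ci + 3 :]
        oracle_prot = str(Seq(edited[: len(edited) - 3]).translate())
        lo = max(0, ci - 15)
        assert ctx.mutant_sequence == oracle_prot[lo : ci + 16]
        assert ctx.wt_sequence in prot  # interior wt window is a substring


# ---------------------------------------------------------------------------
# indel contexts


def _frameshift_setup(codon: int, protein_len: int = 120, seed: int = 7):
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    prot = "M" + "".join(aas[rng.integers(0, 20, protein_len - 1)])
    t = make_transcript(protein=prot, start0=0)
    pos = 3 * (codon - 1) + 1            # first base of the codon
    ref = t.cds_sequence[pos - 1]
    v = variant(pos, ref, ref + "T")     # 1-bp insertion
    e = annotate_effect(v, t)
    assert e.consequence == FRAMESHIFT
    return t, e


def test_frameshift_context_has_24_upstream_residues():
    t, e = _frameshift_setup(codon=50)
    ctx = build_indel_context(e, t)
    assert ctx.is_indel
    assert ctx.mutated_index - 1 == 24          # unaltered residues before novel ORF
    assert ctx.mutant_sequence[:24] == t.protein_sequence[49 - 24 : 49]
    assert "*" not in ctx.mutant_sequence
    novel = ctx.mutant_sequence[24:]
    assert len(novel) >= 1


def test_frameshift_near_terminus_truncates_upstream():
    t, e = _frameshift_setup(codon=10)
    ctx = build_indel_context(e, t)
    assert ctx.mutated_index - 1 == 9


def test_indel_disabled_by_default_in_pipeline():
    from neopept.config import PipelineConfig

    assert PipelineConfig().indel_contexts is False


# ---------------------------------------------------------------------------
# customized proteome + MS flags


def _proteome_text(transcripts, effects, tmp_path, name):
    path = tmp_path / name
    build_custom_proteome(transcripts, effects, path)
    return path.read_text()


def test_zero_variant_roundtrip(tmp_path):
    ts = [make_transcript(protein="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", transcript_id="T1"),
          make_transcript(protein="MDDDIAALVVDNGSGMCKAGFAGDDAPRAVFPS", transcript_id="T2")]
    assert _proteome_text(ts, {}, tmp_path, "a.fa") == _proteome_text(ts, None, tmp_path, "b.fa")
    assert _proteome_text(ts, {}, tmp_path, "c.fa").count(">") == 2


def test_single_missense_adds_tagged_entry(tmp_path):
    t = make_transcript(protein="MKTAYIAKQR", transcript_id="T1", gene_symbol="G1")
    from neopept.annotate import ProteinEffect

    eff = ProteinEffect("T1", "G1", 2, "K", "R", "p.Lys2Arg", MISSENSE)
    text = _proteome_text([t], {"T1": [eff]}, tmp_path, "a.fa")
    assert ">T1|G1\nMKTAYIAKQR" in text
    assert ">T1|G1|p.Lys2Arg\nMRTAYIAKQR" in text


def test_two_phased_edits_single_entry(tmp_path):
    t = make_transcript(protein="MKTAYIAKQR", transcript_id="T1", gene_symbol="G1")
    from neopept.annotate import ProteinEffect

    effs = [ProteinEffect("T1", "G1", 8, "K", "N", "p.Lys8Asn", MISSENSE),
            ProteinEffect("T1", "G1", 2, "K", "R", "p.Lys2Arg", MISSENSE)]
    text = _proteome_text([t], {"T1": effs}, tmp_path, "a.fa")
    assert text.count(">T1|G1|") == 1
    assert ">T1|G1|p.Lys2Arg;p.Lys8Asn\nMRTAYIANQR" in text


def test_flag_observed_peptides():
    t1 = make_transcript(protein="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", transcript_id="T1")
    t2 = make_transcript(protein="MDDDIAALVVDNGSGMCKAGFAGDDAPRAVFPS", transcript_id="T2")
    from neopept.annotate import ProteinEffect

    eff = ProteinEffect("T1", "G1", 10, "R", "W", "p.Arg10Trp", MISSENSE)
    flags = flag_observed_mutant_peptides(
        ["TAYIAKQWQIS",   # spans the substituted residue, absent from reference
         "DNGSGMCKA",     # unmutated region of T2
         "QQQQQQQQQ",     # not a substring of anything
         "TAYIAKQ[1]"],   # non-standard residues
        [t1, t2],
        {"T1": [eff]},
    )
    assert flags["TAYIAKQWQIS"] == "mutant"
    assert flags["DNGSGMCKA"] == "wt"
    assert flags["QQQQQQQQQ"] == "unmapped"
    assert flags["TAYIAKQ[1]"] == "unmapped"
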