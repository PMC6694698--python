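"""Transcript models, protein effect calls and mutant peptide contexts.

Maps retained variants onto protein-coding transcripts, calls codon-level
effects, and builds the mutant context each candidate epitope is enumerated
from: for a missense SNV the novel residue is placed at the center of a
31-mer (15 reference residues either side, truncated at the protein termini,
never padded), with amino-acid changes from non-synonymous phase-linked SNPs
applied inside the window.  For a frameshift indel (optional, off by default)
the context is the 24 unaltered residues immediately upstream of the first
novel residue followed by the novel open-reading-frame translation up to the
first stop.

Also emits the customized proteome FASTA used for proteogenomic MS searches
(mutation tags appended to the headers of affected transcripts) and flags
externally identified MS peptides as mutant / wt / unmapped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from neopept.variants import ConsensusVariant

log = logging.getLogger(__name__)

MISSENSE = "missense"
SYNONYMOUS = "synonymous"
FRAMESHIFT = "frameshift"
INFRAME_INDEL = "inframe_indel"
STOP_GAINED = "stop_gained"

_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")


class TranscriptLoadError(Exception):
    """CDS/FASTA mismatch or unusable transcript annotation."""


@dataclass
class TranscriptModel:
    """A protein-coding transcript with spliced CDS and translation.

    Genomic intervals are stored 0-based half-open and ordered by genomic
    coordinate; 1-based inclusive on input (GFF3 convention).
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str                      # "+" or "-"
    exons: list = field(default_factory=list)   # [(start0, end0), ...]
    cds: list = field(default_factory=list)     # [(start0, end0), ...]
    cds_sequence: str = ""           # coding orientation (already revcomp on "-")
    protein_sequence: str = ""
    incomplete: bool = False

    @property
    def cds_len(self) -> int:
        return len(self.cds_sequence)

    def cds_offset_of(self, pos0: int) -> int | None:
        """Map a 0-based genomic position to its 0-based offset in the coding
        sequence (coding orientation), or None if outside the CDS."""
        off = 0
        if self.strand == "+":
            for s, e in self.cds:
                if s <= pos0 < e:
                    return off + (pos0 - s)
                off += e - s
        else:
            for s, e in reversed(self.cds):
                if s <= pos0 < e:
                    return off + (e - 1 - pos0)
                off += e - s
        return None


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


def load_transcripts(
    gff3: str | Path,
    sequences: str | Path,
    mode: str = "genome",
) -> list[TranscriptModel]:
    """Build one :class:`TranscriptModel` per protein-coding transcript.

    ``mode="genome"``: the FASTA holds chromosome sequences and the CDS is
    spliced from the annotated intervals (minus-strand CDS reverse-
    complemented before translation). ``mode="cds"``: the FASTA holds one
    spliced CDS per transcript, keyed by transcript id.

    Transcripts whose CDS length is not divisible by 3 (or with internal
    stops) are flagged ``incomplete`` and excluded from context building.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(sequences), "fasta")}
    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    for tr in db.features_of_type(("mRNA", "transcript")):
        cds_feats = sorted(db.children(tr, featuretype="CDS"), key=lambda f: f.start)
        if not cds_feats:
            continue
        exon_feats = sorted(db.children(tr, featuretype="exon"), key=lambda f: f.start)
        gene_symbol = tr.attributes.get("gene_name", tr.attributes.get("gene_id", [""]))[0]
        if not gene_symbol:
            parents = list(db.parents(tr, featuretype="gene"))
            if parents:
                p = parents[0]
                gene_symbol = p.attributes.get("gene_name", p.attributes.get("Name", [p.id]))[0]
        model = TranscriptModel(
            transcript_id=tr.id,
            gene_symbol=gene_symbol or tr.id,
            chrom=tr.seqid,
            strand=tr.strand,
            exons=[(f.start - 1, f.end) for f in exon_feats],
            cds=[(f.start - 1, f.end) for f in cds_feats],
        )
        if mode == "cds":
            if tr.id not in seqs:
                raise TranscriptLoadError(f"transcript {tr.id}: no CDS sequence in FASTA")
            cds_seq = seqs[tr.id]
        else:
            if tr.seqid not in seqs:
                raise TranscriptLoadError(f"transcript {tr.id}: chromosome {tr.seqid} not in FASTA")
            chrom_seq = seqs[tr.seqid]
            if model.cds[-1][1] > len(chrom_seq):
                raise TranscriptLoadError(f"transcript {tr.id}: CDS beyond end of {tr.seqid}")
            cds_seq = "".join(chrom_seq[s:e] for s, e in model.cds)
            if tr.strand == "-":
                cds_seq = str(Seq(cds_seq).reverse_complement())
        model.cds_sequence = cds_seq
        if len(cds_seq) % 3 != 0:
            model.incomplete = True
            log.warning("transcript %s: CDS length %d not divisible by 3; excluded from contexts",
                        tr.id, len(cds_seq))
        else:
            prot = _translate(cds_seq)
            if prot.endswith("*"):
                prot = prot[:-1]
            if "*" in prot:
                model.incomplete = True
                log.warning("transcript %s: internal stop; excluded from contexts", tr.id)
            model.protein_sequence = prot
        models.append(model)
    models.sort(key=lambda m: m.transcript_id)
    return models


def canonical_transcripts(models: Sequence[TranscriptModel]) -> dict[str, TranscriptModel]:
    """One transcript per gene: longest CDS, ties broken lexicographically."""
    best: dict[str, TranscriptModel] = {}
    for m in sorted(models, key=lambda m: (-m.cds_len, m.transcript_id)):
        best.setdefault(m.gene_symbol, m)
    return best


@dataclass
class ProteinEffect:
    """Protein-level consequence of one variant on one transcript."""

    transcript_id: str
    gene_symbol: str
    aa_pos: int            # 1-based protein position
    wt_aa: str
    mut_aa: str
    hgvs_label: str        # e.g. p.Tyr749Asp
    consequence: str
    variant: ConsensusVariant | None = None
    cds_offset: int | None = None


_COMP = str.maketrans("ACGT", "TGCA")


def annotate_effect(v: ConsensusVariant, t: TranscriptModel) -> ProteinEffect | None:
    """Codon-level effect of *v* on *t*; None if outside the CDS or the
    transcript is flagged incomplete."""
    if t.incomplete:
        return None
    pos0 = v.pos - 1
    off = t.cds_offset_of(pos0)
    if off is None:
        return None
    if v.is_snv:
        ref_base, alt_base = v.ref, v.alt
        if t.strand == "-":
            ref_base = ref_base.translate(_COMP)
            alt_base = alt_base.translate(_COMP)
        if t.cds_sequence[off] != ref_base:
            warnings.warn(
                f"{v.variant_id}: ref allele disagrees with CDS of {t.transcript_id}",
                stacklevel=2,
            )
        ci = off // 3
        codon = t.cds_sequence[3 * ci : 3 * ci + 3]
        mut_codon = codon[: off % 3] + alt_base + codon[off % 3 + 1 :]
        wt_aa = _translate(codon)
        mut_aa = _translate(mut_codon)
        if mut_aa == wt_aa:
            consequence = SYNONYMOUS
        elif mut_aa == "*":
            consequence = STOP_GAINED
        else:
            consequence = MISSENSE
        label = f"p.{seq3(wt_aa)}{ci + 1}{'Ter' if mut_aa == '*' else seq3(mut_aa)}"
        return ProteinEffect(
            transcript_id=t.transcript_id,
            gene_symbol=t.gene_symbol,
            aa_pos=ci + 1,
            wt_aa=wt_aa,
            mut_aa=mut_aa,
            hgvs_label=label,
            consequence=consequence,
            variant=v,
            cds_offset=off,
        )
    # indel: frame from length difference
    delta = len(v.alt) - len(v.ref)
    ci = off // 3
    wt_aa = t.protein_sequence[ci] if ci < len(t.protein_sequence) else ""
    if delta % 3 == 0:
        consequence = INFRAME_INDEL
        label = f"p.{seq3(wt_aa)}{ci + 1}delins" if wt_aa else f"p.{ci + 1}delins"
    else:
        consequence = FRAMESHIFT
        label = f"p.{seq3(wt_aa)}{ci + 1}fs" if wt_aa else f"p.{ci + 1}fs"
    return ProteinEffect(
        transcript_id=t.transcript_id,
        gene_symbol=t.gene_symbol,
        aa_pos=ci + 1,
        wt_aa=wt_aa,
        mut_aa="",
        hgvs_label=label,
        consequence=consequence,
        variant=v,
        cds_offset=off,
    )


@dataclass
class MutantContext:
    """The mutant peptide context candidate epitopes are enumerated from."""

    mutation_id: str
    gene_symbol: str
    transcript_id: str
    mutant_sequence: str
    wt_sequence: str
    mutated_index: int                      # 1-based within the context
    protein_start: int                      # 1-based start of context in protein
    applied_linked_edits: list = field(default_factory=list)  # [(index, wt, mut)]
    hgvs_label: str = ""
    is_indel: bool = False
    truncated_orf: bool = False             # frameshift hit an immediate stop

    def __len__(self) -> int:
        return len(self.mutant_sequence)


def build_snv_context(
    e: ProteinEffect,
    t: TranscriptModel,
    linked: Sequence[ProteinEffect] = (),
    flank: int = 15,
) -> MutantContext:
    """Center the novel residue in a (2*flank+1)-mer window of the protein.

    The window is truncated (never padded) at the termini.  Every
    non-synonymous linked-SNP edit falling inside the window is applied to
    the mutant sequence; the wt sequence keeps reference residues.
    """
    if e.consequence != MISSENSE:
        raise ValueError(f"{e.hgvs_label}: SNV context requires a missense effect")
    prot = t.protein_sequence
    p = e.aa_pos
    if not 1 <= p <= len(prot):
        raise ValueError(f"{e.hgvs_label}: position outside protein of {t.transcript_id}")
    lo = max(1, p - flank)
    hi = min(len(prot), p + flank)
    wt = prot[lo - 1 : hi]
    mutated_index = p - lo + 1
    mut = list(wt)
    mut[mutated_index - 1] = e.mut_aa
    applied: list[tuple] = []
    for le in sorted(linked, key=lambda x: x.aa_pos):
        if le.consequence != MISSENSE or le.aa_pos == p:
            continue
        if lo <= le.aa_pos <= hi:
            idx = le.aa_pos - lo + 1
            mut[idx - 1] = le.mut_aa
            applied.append((idx, le.wt_aa, le.mut_aa))
    vid = e.variant.variant_id if e.variant is not None else f"{t.transcript_id}:{e.hgvs_label}"
    return MutantContext(
        mutation_id=vid,
        gene_symbol=e.gene_symbol,
        transcript_id=e.transcript_id,
        mutant_sequence="".join(mut),
        wt_sequence=wt,
        mutated_index=mutated_index,
        protein_start=lo,
        applied_linked_edits=applied,
        hgvs_label=e.hgvs_label,
    )


def _apply_indel_to_cds(t: TranscriptModel, v: ConsensusVariant, off: int) -> str:
    """Apply a normalized indel to the coding sequence (plus-strand anchored)."""
    cds = t.cds_sequence
    if t.strand == "-":
        # anchor maps to the coding-strand position of the *last* ref base
        ref = str(Seq(v.ref).reverse_complement())
        alt = str(Seq(v.alt).reverse_complement())
        start = off - (len(v.ref) - 1)
    else:
        ref, alt = v.ref, v.alt
        start = off
    if start < 0:
        raise ValueError(f"{v.variant_id}: indel extends outside the CDS")
    if cds[start : start + len(ref)] != ref:
        warnings.warn(f"{v.variant_id}: ref allele disagrees with CDS of {t.transcript_id}",
                      stacklevel=2)
    return cds[:start] + alt + cds[start + len(ref):]


def build_indel_context(
    e: ProteinEffect,
    t: TranscriptModel,
    upstream: int = 24,
) -> MutantContext:
    """Frameshift context: *upstream* unaltered residues (fewer near the
    N-terminus) followed by the novel ORF translation up to, not including,
    the first stop.  An immediate stop leaves the upstream residues only,
    flagged ``truncated_orf``."""
    if e.consequence not in (FRAMESHIFT, INFRAME_INDEL):
        raise ValueError(f"{e.hgvs_label}: indel context requires an indel effect")
    if e.variant is None or e.cds_offset is None:
        raise ValueError(f"{e.hgvs_label}: effect lacks its source variant")
    mut_cds = _apply_indel_to_cds(t, e.variant, e.cds_offset)
    mut_prot = _translate(mut_cds[: len(mut_cds) - len(mut_cds) % 3])
    ref_prot = t.protein_sequence
    first = None
    for i in range(len(mut_prot)):
        if i >= len(ref_prot) or mut_prot[i] != ref_prot[i]:
            first = i
            break
    if first is None:
        raise ValueError(f"{e.hgvs_label}: indel does not alter the protein")
    novel = mut_prot[first:]
    stop = novel.find("*")
    if stop >= 0:
        novel = novel[:stop]
    up = ref_prot[max(0, first - upstream) : first]
    truncated = novel == ""
    if truncated:
        warnings.warn(f"{e.hgvs_label}: immediate stop after frameshift; upstream-only context",
                      stacklevel=2)
    vid = e.variant.variant_id
    return MutantContext(
        mutation_id=vid,
        gene_symbol=e.gene_symbol,
        transcript_id=e.transcript_id,
        mutant_sequence=up + novel,
        wt_sequence=ref_prot[max(0, first - upstream) : first + len(novel)],
        mutated_index=len(up) + 1,
        protein_start=max(0, first - upstream) + 1,
        hgvs_label=e.hgvs_label,
        is_indel=True,
        truncated_orf=truncated,
    )


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def build_custom_proteome(
    transcripts: Sequence[TranscriptModel],
    effects_by_transcript: dict[str, Sequence[ProteinEffect]] | None,
    path: str | Path,
) -> None:
    """Write the customized proteome FASTA.

    Every reference protein is emitted once (``>tid|gene``); each affected
    transcript is additionally emitted with the full mutant sequence and a
    header suffix listing its non-synonymous substitutions
    (``>tid|gene|p.Xaa#Yaa;...``, pipe-delimited, edits sorted by position).
    With zero variants the output is identical to the reference proteome.
    """
    effects_by_transcript = effects_by_transcript or {}
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda m: m.transcript_id):
            if not t.protein_sequence:
                continue
            fh.write(f">{t.transcript_id}|{t.gene_symbol}\n{_wrap(t.protein_sequence)}\n")
            effs = [
                e
                for e in effects_by_transcript.get(t.transcript_id, [])
                if e.consequence == MISSENSE
            ]
            if not effs:
                continue
            mut = list(t.protein_sequence)
            tags = []
            for e in sorted(effs, key=lambda e: e.aa_pos):
                mut[e.aa_pos - 1] = e.mut_aa
                tags.append(e.hgvs_label)
            fh.write(
                f">{t.transcript_id}|{t.gene_symbol}|{';'.join(tags)}\n{_wrap(''.join(mut))}\n"
            )


def flag_observed_mutant_peptides(
    peptides: Iterable[str],
    transcripts: Sequence[TranscriptModel],
    effects_by_transcript: dict[str, Sequence[ProteinEffect]],
) -> dict[str, str]:
    """Flag MS-identified peptides as ``mutant`` / ``wt`` / ``unmapped``.

    A peptide is ``mutant`` iff it occurs in a mutant protein at an offset
    spanning a mutated residue and occurs nowhere in the reference proteome;
    ``wt`` if found in the reference proteome; otherwise ``unmapped``.
    """
    ref_blob = "|".join(t.protein_sequence for t in transcripts if t.protein_sequence)
    mutants: list[tuple[str, set[int]]] = []  # (mutant protein, 0-based mutated indices)
    for t in transcripts:
        effs = [
            e for e in effects_by_transcript.get(t.transcript_id, [])
            if e.consequence == MISSENSE
        ]
        if not effs or not t.protein_sequence:
            continue
        mut = list(t.protein_sequence)
        idxs = set()
        for e in effs:
            mut[e.aa_pos - 1] = e.mut_aa
            idxs.add(e.aa_pos - 1)
        mutants.append(("".join(mut), idxs))

    flags: dict[str, str] = {}
    for pep in peptides:
        pep = pep.strip().upper()
        if not pep or not _AA20.issuperset(pep):
            flags[pep] = "unmapped"
            continue
        if pep in ref_blob:
            flags[pep] = "wt"
            continue
        is_mutant = False
        for mseq, idxs in mutants:
            start = mseq.find(pep)
            while start >= 0 and not is_mutant:
                if any(start <= i < start + len(pep) for i in idxs):
                    is_mutant = True
                start = mseq.find(pep, start + 1)
            if is_mutant:
                break
        flags[pep] = "mutant" if is_mutant else "unmapped"
    return flags
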