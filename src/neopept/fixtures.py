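"""Seeded synthetic input bundles with planted ground truth.

Generates a self-consistent toy world on disk — single-chromosome genome,
one-exon plus-strand transcripts, three per-caller VCFs with planted
concordance/discordance and phasing, an expression table, a ligand database,
PWM motif files, a driver list — plus a truth JSON recording what the
pipeline is expected to do with it (high-confidence selection, filter
outcomes, the engineered rank-1 mutation).

Planting strategy: allele PWMs carry high-weight anchor residues; designated
mutations create epitopes by substituting an anchor residue (Pro→Leu at the
class I position-2 anchor) inside a window whose remaining anchors are
already present in the germline protein.  The designated best mutation
matches every class I anchor, other planted binders only two, so the best
mutation's percentile rank is strictly the minimum among planted binders —
verified against the generated decoy distribution at build time.

Defaults emulate the smallest of the three published patients: 23
non-synonymous somatic mutations in a low-mutational-load tumor, two HLA-I
and one HLA-II allotype, pancreas as the target tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Data import CodonTable
from Bio.Seq import Seq

from neopept.binding import AMINO_ACIDS, CORE_LEN, PwmModel

HLA_I_ALLELES = ("A0101", "A0201")
HLA_II_ALLELES = ("DRB10101",)

# class I anchors (positions 2, 3, 4 and C-terminus); the planted best
# mutation matches all four, other planted binders only 2 and C-terminus
_A0101_ANCHORS = {2: "L", 3: "A", 4: "G", -1: "V"}
_A0201_ANCHORS = {2: "M", -1: "K"}
# class II 9-mer core anchors (mutation sits on the position-5 anchor)
_DRB1_ANCHORS = {1: "W", 5: "L", 9: "E"}

_ANCHOR_WEIGHT = 0.8


class FixtureError(Exception):
    """Impossible fixture specification or violated planting invariant."""


@dataclass
class FixtureSpec:
    """Parameters of the synthetic world; defaults are the stated conditions."""

    seed: int = 1
    n_genes: int = 20
    protein_length_range: tuple = (120, 260)
    n_somatic: int = 23
    fraction_phased_linked: float = 0.2
    n_db_ligands: int = 120
    n_germline_noise: int = 6
    hypermutated_count: int = 5        # somatic SNVs planted in one gene
    decoy_n: int = 100_000
    decoy_seed: int = 42
    rank_cutoff: float = 5.0
    tissue: str = "pancreas"
    minus_strand_fraction: float = 0.0
    caller_concordance_profile: list | None = None

    def validate(self) -> None:
        lo, hi = self.protein_length_range
        if lo < 60 or hi < lo:
            raise FixtureError("protein_length_range too small for epitope planting")
        if self.hypermutated_count < 4:
            raise FixtureError("hypermutated_count must exceed the default gene cap (3)")
        minimum = 4 + self.hypermutated_count + 2 + 1 + 1  # planted+hyper+low-support+conflict+1 normal
        if self.n_somatic < minimum:
            raise FixtureError(
                f"n_somatic must be >= {minimum} to place all planted roles"
            )
        if self.n_genes < 8:
            raise FixtureError("need >= 8 genes for the planted roles")
        capacity = (self.n_genes - 2) * 3 + self.hypermutated_count
        if self.n_somatic > capacity:
            raise FixtureError(
                f"more somatic SNVs ({self.n_somatic}) than available codon budget"
            )
        if not 0 <= self.fraction_phased_linked <= 1:
            raise FixtureError("fraction_phased_linked must be in [0, 1]")


# ---------------------------------------------------------------------------
# codon helpers

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)


def _codon_for(aa: str, rng: np.random.Generator) -> str:
    codons = _AA_TO_CODONS[aa]
    return codons[rng.integers(len(codons))]


def _missense_edit(codon: str, rng: np.random.Generator) -> tuple[int, str, str]:
    """(codon_position, alt_base, mut_aa) for a random single-base missense."""
    wt_aa = _TABLE.forward_table.get(codon)
    options = []
    for cp in range(3):
        for base in "ACGT":
            if base == codon[cp]:
                continue
            mut = codon[:cp] + base + codon[cp + 1 :]
            aa = _TABLE.forward_table.get(mut)  # None for stop codons
            if aa is not None and aa != wt_aa:
                options.append((cp, base, aa))
    if not options:
        raise FixtureError(f"codon {codon} admits no missense edit")
    return options[rng.integers(len(options))]


# ---------------------------------------------------------------------------
# PWM construction

def _anchor_row(anchor: str, jitter: np.ndarray | None = None) -> np.ndarray:
    row = np.full(20, (1.0 - _ANCHOR_WEIGHT) / 19)
    row[AMINO_ACIDS.index(anchor)] = _ANCHOR_WEIGHT
    return row


def _background_row(rng: np.random.Generator) -> np.ndarray:
    row = 0.05 + rng.uniform(-0.004, 0.004, size=20)
    return row / row.sum()


def build_pwm_models(rng: np.random.Generator) -> list[PwmModel]:
    """The built-in allele motifs of the synthetic world.

    Rows are normalized to sum to 1; anchor rows concentrate weight on one
    residue, background rows are near-uniform with deterministic jitter.
    """
    models = []
    for allele, anchors in (("A0101", _A0101_ANCHORS), ("A0201", _A0201_ANCHORS)):
        m = PwmModel(allele=allele, hla_class="I")
        for k in (9, 10, 11, 12):
            mat = np.vstack([_background_row(rng) for _ in range(k)])
            for pos, aa in anchors.items():
                idx = k - 1 if pos == -1 else pos - 1
                mat[idx] = _anchor_row(aa)
            m.matrices[k] = mat
        models.append(m)
    for allele in HLA_II_ALLELES:
        m = PwmModel(allele=allele, hla_class="II")
        core = np.vstack([_background_row(rng) for _ in range(CORE_LEN)])
        for pos, aa in _DRB1_ANCHORS.items():
            core[pos - 1] = _anchor_row(aa)
        m.core = core
        models.append(m)
    return models


# ---------------------------------------------------------------------------
# draft world

@dataclass
class PlannedVariant:
    """One planted variant of the synthetic tumor."""

    gene_idx: int
    aa_pos: int                 # 1-based codon index
    codon_pos: int              # 0..2
    ref_base: str = ""
    alt_base: str = ""
    wt_aa: str = ""
    mut_aa: str = ""
    somatic: bool = True
    supporters: tuple = ("gatk", "mutect", "varscan")
    role: str = "normal"        # best|planted|wt_trap|low_tpm|hyper|normal|
                                # low_support|conflict|germline|linked|opposite
    phase_set: str | None = None
    haplotype: int | None = None
    partner: int | None = None  # index of the somatic partner (linked SNPs)
    genomic_pos: int = 0        # 1-based, filled at layout time
    variant_id: str = ""
    conflict_alt: str | None = None  # discordant ALT reported by the odd caller


@dataclass
class CohortDraft:
    spec: FixtureSpec
    gene_ids: list = field(default_factory=list)
    transcript_ids: list = field(default_factory=list)
    proteins: list = field(default_factory=list)       # germline aa sequences
    variants: list = field(default_factory=list)       # PlannedVariant
    rejected: list = field(default_factory=list)       # 1v1 conflict coordinate
    models: list = field(default_factory=list)
    planted_best_idx: int | None = None
    planted_binder_idxs: list = field(default_factory=list)
    wt_trap_peptide: str = ""
    low_tpm_gene: str = ""
    hyper_gene: str = ""


def _plant_epitope(
    protein: list,
    a: int,
    rng: np.random.Generator,
    best: bool,
) -> None:
    """Engineer germline residues around 1-based codon *a* so that the
    mutant Pro→Leu substitution at *a* creates the planted epitopes."""
    protein[a - 1] = "P"                       # wt; mutant becomes L (anchor 2)
    protein[a] = "A" if best else "S"          # class I anchor 3 (best only)
    protein[a + 1] = "G" if best else "T"      # class I anchor 4 (best only)
    protein[a + 6] = "V"                       # class I C-terminal anchor
    protein[a - 5] = "W"                       # class II core anchor 1
    protein[a + 3] = "E"                       # class II core anchor 9


def _draft_cohort(spec: FixtureSpec, rng: np.random.Generator) -> CohortDraft:
    spec.validate()
    lo, hi = spec.protein_length_range
    draft = CohortDraft(spec=spec)
    aa = np.array(list(AMINO_ACIDS))
    for i in range(spec.n_genes):
        L = int(rng.integers(lo, hi + 1))
        draft.gene_ids.append(f"GENE{i + 1:03d}")
        draft.transcript_ids.append(f"TR{i + 1:03d}")
        draft.proteins.append(list(aa[rng.integers(0, 20, size=L)]))

    # --- role layout -------------------------------------------------------
    # genes: 0 best, 1 planted, 2 wt-trap planted, 3 low-TPM planted,
    #        4 hypermutated, 5 trap host (no mutations), 6.. normal pool
    hyper_n = spec.hypermutated_count
    n_special = 4 + hyper_n + 2 + 1            # planted(4) + hyper + low-support(2) + conflict(1)
    n_normal = spec.n_somatic - n_special
    if n_normal < 1:
        raise FixtureError("n_somatic leaves no room for unplanted mutations")

    used: dict[int, set] = {}

    def interior_site(gene_idx: int, margin: int = 20) -> int:
        L = len(draft.proteins[gene_idx])
        return int(rng.integers(margin, L - margin))

    def fresh_site(g: int) -> int:
        while True:
            a = interior_site(g)
            if a not in used.setdefault(g, set()):
                used[g].add(a)
                return a

    planted_roles = [("best", 0), ("planted", 1), ("wt_trap", 2), ("low_tpm", 3)]
    for role, g in planted_roles:
        a = fresh_site(g)
        # keep the whole epitope window clear of other planted sites
        used[g].update(range(a - 8, a + 9))
        _plant_epitope(draft.proteins[g], a, rng, best=(role == "best"))
        pv = PlannedVariant(gene_idx=g, aa_pos=a, codon_pos=1, role=role,
                            wt_aa="P", mut_aa="L")
        draft.variants.append(pv)
        draft.planted_binder_idxs.append(len(draft.variants) - 1)
        if role == "best":
            draft.planted_best_idx = len(draft.variants) - 1
    draft.low_tpm_gene = draft.gene_ids[3]
    draft.hyper_gene = draft.gene_ids[4]

    # hypermutated gene: hyper_n ordinary missense SNVs
    for _ in range(hyper_n):
        draft.variants.append(
            PlannedVariant(gene_idx=4, aa_pos=fresh_site(4), codon_pos=-1, role="hyper")
        )

    # low-support traps (single non-MuTect caller -> excluded)
    normal_pool = list(range(6, spec.n_genes))
    for supp in (("gatk",), ("varscan",)):
        g = normal_pool[int(rng.integers(len(normal_pool)))]
        draft.variants.append(
            PlannedVariant(gene_idx=g, aa_pos=fresh_site(g), codon_pos=-1,
                           role="low_support", supporters=supp)
        )

    # majority-resolved conflict: mutect+varscan agree, gatk reports another ALT
    g = normal_pool[int(rng.integers(len(normal_pool)))]
    draft.variants.append(
        PlannedVariant(gene_idx=g, aa_pos=fresh_site(g), codon_pos=-1,
                       role="conflict", supporters=("mutect", "varscan"))
    )

    # ordinary somatic mutations, <=3 per gene
    hc_profiles = [("mutect",), ("mutect", "varscan"), ("gatk", "mutect"),
                   ("gatk", "varscan"), ("gatk", "mutect", "varscan")]
    profiles = (
        list(spec.caller_concordance_profile)
        if spec.caller_concordance_profile
        else hc_profiles
    )
    per_gene: dict[int, int] = {}
    gi = 0
    normal_idxs = []
    for j in range(n_normal):
        for _ in range(len(normal_pool) + 1):
            g = normal_pool[gi % len(normal_pool)]
            gi += 1
            if per_gene.get(g, 0) < 3:
                break
        per_gene[g] = per_gene.get(g, 0) + 1
        draft.variants.append(
            PlannedVariant(gene_idx=g, aa_pos=fresh_site(g), codon_pos=-1,
                           role="normal", supporters=tuple(profiles[j % len(profiles)]))
        )
        normal_idxs.append(len(draft.variants) - 1)

    # phase-linked germline SNPs on a fraction of the ordinary mutations
    n_linked = int(round(spec.fraction_phased_linked * len(normal_idxs)))
    for j, si in enumerate(normal_idxs[:n_linked]):
        sv = draft.variants[si]
        ps = f"{1000 + j}"
        sv.phase_set, sv.haplotype = ps, 1
        offset = int(rng.integers(2, 11)) * (1 if rng.random() < 0.5 else -1)
        a = sv.aa_pos + offset
        a = max(2, min(len(draft.proteins[sv.gene_idx]) - 1, a))
        if a in used.setdefault(sv.gene_idx, set()) or a == sv.aa_pos:
            a = fresh_site(sv.gene_idx)
        else:
            used[sv.gene_idx].add(a)
        draft.variants.append(
            PlannedVariant(gene_idx=sv.gene_idx, aa_pos=a, codon_pos=-1,
                           somatic=False, role="linked", phase_set=ps, haplotype=1,
                           partner=si)
        )
    # one opposite-haplotype germline SNP: phased with a somatic, other allele
    if len(normal_idxs) > n_linked:
        si = normal_idxs[n_linked]
        sv = draft.variants[si]
        ps = "2000"
        sv.phase_set, sv.haplotype = ps, 1
        draft.variants.append(
            PlannedVariant(gene_idx=sv.gene_idx, aa_pos=fresh_site(sv.gene_idx),
                           codon_pos=-1, somatic=False, role="opposite",
                           phase_set=ps, haplotype=0, partner=si)
        )

    # unphased germline noise SNPs
    for _ in range(spec.n_germline_noise):
        g = int(rng.integers(spec.n_genes))
        draft.variants.append(
            PlannedVariant(gene_idx=g, aa_pos=fresh_site(g), codon_pos=-1,
                           somatic=False, role="germline")
        )

    # rejected 1v1 conflict coordinate (mutect vs gatk, no majority)
    g = normal_pool[int(rng.integers(len(normal_pool)))]
    draft.rejected.append(
        PlannedVariant(gene_idx=g, aa_pos=fresh_site(g), codon_pos=-1, role="rejected")
    )
    return draft


def plant_neoantigens(spec: FixtureSpec, draft: CohortDraft,
                      rng: np.random.Generator) -> CohortDraft:
    """Build the allele motifs, duplicate the wt-trap peptide, and verify the
    planting invariant: every planted mutant epitope scores below the binder
    cutoff against the generated decoy distribution, and the designated best
    mutation's percentile rank is strictly the minimum among planted binders.
    """
    draft.models = build_pwm_models(rng)
    for ai, m in enumerate(draft.models):
        m.generate_decoys(np.random.default_rng([spec.decoy_seed, ai]),
                          spec.decoy_n, (9, 10, 11, 12) if m.hla_class == "I"
                          else (12, 13, 14, 15, 16, 17, 18, 19))

    # mutant class I 9-mer epitope of each planted mutation (protein coords
    # [a-1, a+7], mutation at epitope position 2)
    def mutant_epitope(pv: PlannedVariant) -> str:
        prot = draft.proteins[pv.gene_idx]
        window = list(prot[pv.aa_pos - 2 : pv.aa_pos + 7])
        window[1] = "L"
        return "".join(window)

    # wt-identity trap: copy the trap mutation's mutant 9-mer into the
    # (unmutated) host gene so the exact mutant peptide pre-exists elsewhere
    trap = next(v for v in draft.variants if v.role == "wt_trap")
    pep = mutant_epitope(trap)
    host = draft.proteins[5]
    at = len(host) // 2
    host[at : at + len(pep)] = list(pep)
    draft.wt_trap_peptide = pep

    a0101 = next(m for m in draft.models if m.allele == "A0101")
    ranks = {}
    for i in draft.planted_binder_idxs:
        pv = draft.variants[i]
        s = a0101.score(mutant_epitope(pv))
        d = a0101.decoys[9]
        ranks[i] = 100.0 * (len(d) - np.searchsorted(d, s, side="left")) / len(d)
    for i, r in ranks.items():
        if r >= spec.rank_cutoff:
            raise FixtureError(
                f"planted epitope of {draft.variants[i].role} scores %Rank {r:.2f}"
            )
    best_r = ranks[draft.planted_best_idx]
    others = [r for i, r in ranks.items() if i != draft.planted_best_idx]
    if others and best_r >= min(others):
        raise FixtureError("planted best mutation is not strictly the best binder")
    return draft


# ---------------------------------------------------------------------------
# writing the bundle

_SPACER = 50


def _encode_genes(draft: CohortDraft, rng: np.random.Generator) -> tuple[str, list]:
    """Genome sequence plus per-gene (start0, cds_nt) records."""
    bases = np.array(list("ACGT"))
    chunks: list[str] = []
    layout = []
    cursor = 0
    minus = rng.random(len(draft.proteins)) < draft.spec.minus_strand_fraction
    for g, prot in enumerate(draft.proteins):
        spacer = "".join(bases[rng.integers(0, 4, size=_SPACER)])
        chunks.append(spacer)
        cursor += _SPACER
        cds = "".join(_codon_for(aa, rng) for aa in prot) + "TAA"
        strand = "-" if minus[g] else "+"
        chunks.append(cds if strand == "+" else str(Seq(cds).reverse_complement()))
        layout.append({"start0": cursor, "cds": cds, "strand": strand})
        cursor += len(cds)
    return "".join(chunks), layout


def _finalize_variants(draft: CohortDraft, layout: list,
                       rng: np.random.Generator) -> None:
    """Fix codons/bases and genomic coordinates for every planned variant."""
    for pv in draft.variants + draft.rejected:
        rec = layout[pv.gene_idx]
        cds = rec["cds"]
        ci = pv.aa_pos - 1
        codon = cds[3 * ci : 3 * ci + 3]
        if pv.role in ("best", "planted", "wt_trap", "low_tpm"):
            # Pro(CCN) -> Leu(CTN): single base at codon position 2
            if _TABLE.forward_table[codon] != "P":   # pragma: no cover
                raise FixtureError("planted site lost its proline")
            cp, alt, mut_aa = 1, "T", "L"
        else:
            cp, alt, mut_aa = _missense_edit(codon, rng)
        pv.codon_pos = cp
        pv.ref_base = codon[cp]
        pv.alt_base = alt
        pv.wt_aa = _TABLE.forward_table[codon]
        pv.mut_aa = mut_aa
        off = 3 * ci + cp
        if rec["strand"] == "+":
            pos0 = rec["start0"] + off
            ref, altb = pv.ref_base, pv.alt_base
        else:
            pos0 = rec["start0"] + (len(cds) - 1 - off)
            comp = str.maketrans("ACGT", "TGCA")
            ref, altb = pv.ref_base.translate(comp), pv.alt_base.translate(comp)
        pv.ref_base, pv.alt_base = ref, altb
        pv.genomic_pos = pos0 + 1
        pv.variant_id = f"1:{pv.genomic_pos}:{ref}>{altb}"
        if pv.role == "conflict":
            others = [b for b in "ACGT" if b not in (ref, altb)]
            pv.conflict_alt = others[int(rng.integers(len(others)))]


def _vcf_text(draft: CohortDraft, caller: str, contig_len: int) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=1,length={contig_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL",
    ]
    rows = []
    for pv in draft.variants:
        alt = pv.alt_base
        if pv.somatic:
            if caller not in pv.supporters:
                if pv.role == "conflict" and caller == "gatk":
                    alt = pv.conflict_alt
                else:
                    continue
            if pv.phase_set is not None:
                gt = "0|1" if pv.haplotype == 1 else "1|0"
                tum = f"{gt}:{pv.phase_set}"
                fmt = "GT:PS"
                nor = "0/0:."
            else:
                tum, fmt, nor = "0/1", "GT", "0/0"
        else:
            if pv.phase_set is not None:
                gt = "0|1" if pv.haplotype == 1 else "1|0"
                tum = f"{gt}:{pv.phase_set}"
                fmt = "GT:PS"
                nor = "0/1:."
            else:
                tum, fmt, nor = "0/1", "GT", "0/1"
        rows.append((pv.genomic_pos, pv.ref_base, alt, fmt, tum, nor))
    for pv in draft.rejected:
        if caller == "mutect":
            rows.append((pv.genomic_pos, pv.ref_base, pv.alt_base, "GT", "0/1", "0/0"))
        elif caller == "gatk":
            others = [b for b in "ACGT" if b not in (pv.ref_base, pv.alt_base)]
            rows.append((pv.genomic_pos, pv.ref_base, others[0], "GT", "0/1", "0/0"))
    rows.sort()
    for pos, ref, alt, fmt, tum, nor in rows:
        lines.append(f"1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t{tum}\t{nor}")
    return "\n".join(lines) + "\n"


def _gff3_text(draft: CohortDraft, layout: list) -> str:
    lines = ["##gff-version 3"]
    for g, rec in enumerate(layout):
        start = rec["start0"] + 1
        end = rec["start0"] + len(rec["cds"])
        gid, tid = draft.gene_ids[g], draft.transcript_ids[g]
        strand = rec["strand"]
        lines.append(f"1\tneopept\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid};Name={gid}")
        lines.append(
            f"1\tneopept\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={tid};Parent={gid};gene_name={gid}"
        )
        lines.append(
            f"1\tneopept\texon\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={tid}.exon1;Parent={tid}"
        )
        lines.append(
            f"1\tneopept\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
            f"ID={tid}.cds1;Parent={tid}"
        )
    return "\n".join(lines) + "\n"


def _expression_rows(draft: CohortDraft, rng: np.random.Generator) -> list:
    rows = []
    for g, gid in enumerate(draft.gene_ids):
        if gid == draft.low_tpm_gene:
            tpms = rng.uniform(0.05, 0.6, size=8)
        else:
            tpms = rng.uniform(2.0, 60.0, size=8)
        rows.append([gid, draft.spec.tissue, *np.round(tpms, 3)])
    return rows


def _ligand_rows(draft: CohortDraft, rng: np.random.Generator) -> list:
    rows = []
    # deliberate plants: the best mutation's wild-type 9-mer (EXACT for
    # class I) and a wild-type core-containing 14-mer (EXACT for class II)
    best = draft.variants[draft.planted_best_idx]
    prot = "".join(draft.proteins[best.gene_idx])
    tid = draft.transcript_ids[best.gene_idx]
    wt9 = prot[best.aa_pos - 2 : best.aa_pos + 7]
    wt14 = prot[best.aa_pos - 7 : best.aa_pos + 7]
    rows.append([wt9, "I", tid, int(rng.integers(5, 40))])
    rows.append([wt14, "II", tid, int(rng.integers(5, 40))])
    # a same-protein ligand with partial positional overlap for another
    # planted mutation (no containment relation with any 9-12-mer wt form)
    other = draft.variants[draft.planted_binder_idxs[1]]
    oprot = "".join(draft.proteins[other.gene_idx])
    otid = draft.transcript_ids[other.gene_idx]
    lig = oprot[other.aa_pos + 5 : other.aa_pos + 14]
    rows.append([lig, "I", otid, int(rng.integers(1, 20))])
    for _ in range(draft.spec.n_db_ligands):
        g = int(rng.integers(len(draft.proteins)))
        prot = "".join(draft.proteins[g])
        cls = "I" if rng.random() < 0.6 else "II"
        k = int(rng.integers(9, 12)) if cls == "I" else int(rng.integers(13, 17))
        s = int(rng.integers(0, len(prot) - k))
        rows.append([prot[s : s + k], cls, draft.transcript_ids[g],
                     int(rng.integers(1, 40))])
    return rows


def _truth(draft: CohortDraft) -> dict:
    somatic = [pv for pv in draft.variants if pv.somatic]
    records = []
    hc, retained = [], []
    linked_map: dict[str, list] = {}
    for pv in draft.variants:
        if pv.role in ("linked", "opposite") and pv.partner is not None:
            if pv.role == "linked":
                linked_map.setdefault(draft.variants[pv.partner].variant_id, []).append(
                    pv.variant_id
                )
    for pv in somatic:
        high_conf = "mutect" in pv.supporters or len(pv.supporters) >= 2
        filtered = None
        if not high_conf:
            filtered = "low_support"
        elif pv.role == "low_tpm":
            filtered = "expression"
        elif pv.role == "hyper":
            filtered = "hypermutated"
        if high_conf:
            hc.append(pv.variant_id)
        if high_conf and filtered is None:
            retained.append(pv.variant_id)
        records.append(
            {
                "id": pv.variant_id,
                "gene": draft.gene_ids[pv.gene_idx],
                "transcript": draft.transcript_ids[pv.gene_idx],
                "chrom": "1",
                "pos": pv.genomic_pos,
                "ref": pv.ref_base,
                "alt": pv.alt_base,
                "aa_pos": pv.aa_pos,
                "wt_aa": pv.wt_aa,
                "mut_aa": pv.mut_aa,
                "supporters": sorted(pv.supporters),
                "role": pv.role,
                "high_confidence": high_conf,
                "filtered_by": filtered,
                "linked_snps": sorted(linked_map.get(pv.variant_id, [])),
                "planted_binder": pv.role in ("best", "planted", "wt_trap", "low_tpm"),
            }
        )
    best = draft.variants[draft.planted_best_idx]
    return {
        "n_somatic": len(somatic),
        "somatic": records,
        "rejected": [pv.variant_id for pv in draft.rejected],
        "germline": [pv.variant_id for pv in draft.variants if not pv.somatic],
        "planted": {
            "best": best.variant_id,
            "binders": [draft.variants[i].variant_id for i in draft.planted_binder_idxs],
            "wt_trap_peptide": draft.wt_trap_peptide,
            "low_tpm_gene": draft.low_tpm_gene,
            "hypermutated_gene": draft.hyper_gene,
        },
        "expected": {
            "high_confidence": sorted(hc),
            "retained_after_filters": sorted(retained),
            "rank1": best.variant_id,
        },
    }


@dataclass
class FixtureBundle:
    root: Path
    paths: dict
    truth: dict


def generate_cohort(spec: FixtureSpec, outdir: str | Path) -> FixtureBundle:
    """Write the full input bundle; identical bytes for identical seeds."""
    rng = np.random.default_rng(spec.seed)
    draft = _draft_cohort(spec, rng)
    draft = plant_neoantigens(spec, draft, rng)
    genome, layout = _encode_genes(draft, rng)
    _finalize_variants(draft, layout, rng)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "gff3": out / "annotation.gff3",
        "vcf_gatk": out / "gatk.vcf",
        "vcf_mutect": out / "mutect.vcf",
        "vcf_varscan": out / "varscan.vcf",
        "expression": out / "expression.tsv",
        "ligands": out / "ligands.tsv",
        "drivers": out / "drivers.tsv",
        "truth": out / "truth.json",
        "config": out / "config.yaml",
        "pwm_dir": out / "pwm",
    }
    with open(paths["genome"], "w") as fh:
        fh.write(">1\n")
        for i in range(0, len(genome), 60):
            fh.write(genome[i : i + 60] + "\n")
    paths["gff3"].write_text(_gff3_text(draft, layout))
    for caller in ("gatk", "mutect", "varscan"):
        paths[f"vcf_{caller}"].write_text(_vcf_text(draft, caller, len(genome)))
    with open(paths["expression"], "w") as fh:
        cols = ["gene", "tissue"] + [f"s{i + 1}" for i in range(8)]
        fh.write("\t".join(cols) + "\n")
        for row in _expression_rows(draft, rng):
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["ligands"], "w") as fh:
        fh.write("peptide\thla_class\tprotein\tn_observations\n")
        for row in _ligand_rows(draft, rng):
            fh.write("\t".join(str(x) for x in row) + "\n")
    best = draft.variants[draft.planted_best_idx]
    with open(paths["drivers"], "w") as fh:
        fh.write("gene\tstatus\n")
        fh.write(f"{draft.gene_ids[best.gene_idx]}\tDriver\n")
        fh.write(f"{draft.gene_ids[6]}\tPassenger\n")
    paths["pwm_dir"].mkdir(exist_ok=True)
    for m in draft.models:
        m.to_tsv(paths["pwm_dir"] / f"{m.allele}.tsv")
    truth = _truth(draft)
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    cfg = {
        "tumor_sample": "TUMOR",
        "germline_sample": "NORMAL",
        "vcf_gatk": "gatk.vcf",
        "vcf_mutect": "mutect.vcf",
        "vcf_varscan": "varscan.vcf",
        "gff3": "annotation.gff3",
        "genome_fasta": "genome.fasta",
        "fasta_mode": "genome",
        "expression_tsv": "expression.tsv",
        "ligand_db_tsv": "ligands.tsv",
        "pwm_dir": "pwm",
        "driver_tsv": "drivers.tsv",
        "tissue": spec.tissue,
        "decoy_n": spec.decoy_n,
        "decoy_seed": spec.decoy_seed,
        "rank_cutoff": spec.rank_cutoff,
        "alleles_i": list(HLA_I_ALLELES),
        "alleles_ii": list(HLA_II_ALLELES),
    }
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return FixtureBundle(root=out, paths=paths, truth=truth)


class Truth:
    """Accessor over a bundle's ground-truth table."""

    def __init__(self, data: dict):
        self.data = data

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path) -> "Truth":
        path = Path(bundle_dir) / "truth.json"
        if not path.exists():
            raise FileNotFoundError(f"no truth table at {path}")
        return cls(json.loads(path.read_text()))

    @property
    def rank1(self) -> str:
        return self.data["expected"]["rank1"]

    @property
    def n_somatic(self) -> int:
        return self.data["n_somatic"]

    def somatic_ids(self) -> list:
        return [r["id"] for r in self.data["somatic"]]

    def high_confidence_ids(self) -> list:
        return list(self.data["expected"]["high_confidence"])

    def retained_ids(self) -> list:
        return list(self.data["expected"]["retained_after_filters"])

    def filtered(self, reason: str) -> list:
        return [r["id"] for r in self.data["somatic"] if r["filtered_by"] == reason]

    def linked_snps(self, somatic_id: str) -> list:
        for r in self.data["somatic"]:
            if r["id"] == somatic_id:
                return list(r["linked_snps"])
        raise KeyError(somatic_id)


def expected_truth(bundle: FixtureBundle | str | Path) -> Truth:
    """Truth-table accessor for test assertions."""
    if isinstance(bundle, FixtureBundle):
        return Truth(bundle.truth)
    return Truth.from_bundle(bundle)
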