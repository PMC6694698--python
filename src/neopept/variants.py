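"""Three-caller variant consensus.

Builds the non-redundant union call set from per-caller VCFs.  Conflicting
calls at one genomic coordinate are resolved by a simple majority rule: the
allele reported by a strict majority of the callers reporting at that
coordinate is kept; with no strict majority the coordinate is rejected.
Somatic status is tumor-only presence; germline evidence from any caller wins.
High-confidence somatic calls are those reported by MuTect alone or by at
least two of the three callers; germline SNPs phased onto the same haplotype
as a retained somatic variant are attached as linked SNPs and inherit
retention from their somatic partner.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from neopept.config import ConfigurationError

log = logging.getLogger(__name__)

CALLERS = ("gatk", "mutect", "varscan")

SOMATIC = "somatic"
GERMLINE_SNP = "germline_snp"

_BASES = frozenset("ACGT")


class VcfParseError(Exception):
    """Malformed VCF input; message names the offending file/record."""


@dataclass(frozen=True)
class CallerVariant:
    """One ALT allele of one record from one caller's VCF."""

    caller_id: str
    chrom: str
    pos: int               # 1-based
    ref: str
    alt: str
    in_tumor: bool
    in_germline: bool
    phase_set: str | None = None
    haplotype: int | None = None   # index of the ALT in a phased GT, else None

    def __post_init__(self):
        if self.caller_id not in CALLERS:
            raise ValueError(f"unknown caller {self.caller_id!r}")
        if self.pos < 1:
            raise ValueError("pos must be 1-based and >= 1")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError("ref and alt must be nonempty and distinct")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ConsensusVariant:
    """A merged, caller-attributed variant."""

    chrom: str
    pos: int               # 1-based
    ref: str
    alt: str
    supporters: frozenset
    in_tumor: bool
    in_germline: bool
    origin: str | None = None
    high_confidence: bool = False
    phase_set: str | None = None
    haplotype: int | None = None
    linked_snps: list = field(default_factory=list)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def normalize(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: trim shared suffix, then shared prefix.

    Makes (ref, alt) equality well-defined across callers that pad indels
    differently. Keeps at least one base on each side.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _allele_presence(sample) -> set[int]:
    """Return the set of non-reference allele indices carried by a sample."""
    gt = sample.get("GT")
    if gt is None:
        return set()
    return {a for a in gt if a is not None and a > 0}


def parse_caller_vcf(
    path: str | Path,
    caller_id: str,
    tumor_sample: str = "TUMOR",
    germline_sample: str = "NORMAL",
) -> list[CallerVariant]:
    """Read one caller's VCF into per-ALT :class:`CallerVariant` records.

    Multi-allelic records are split; phase annotations (phased GT plus PS
    phase-set tag on the tumor sample) are captured when present.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        for name in (tumor_sample, germline_sample):
            if name not in samples:
                raise ConfigurationError(
                    f"{path}: sample column {name!r} missing (found {samples})"
                )
        out: list[CallerVariant] = []
        for rec in vf:
            if rec.alts is None:
                continue
            tum = rec.samples[tumor_sample]
            ger = rec.samples[germline_sample]
            tum_alleles = _allele_presence(tum)
            ger_alleles = _allele_presence(ger)
            phased = bool(tum.phased)
            ps = tum.get("PS")
            ps = None if ps is None else str(ps)
            for ai, alt in enumerate(rec.alts, start=1):
                if alt is None or not _BASES.issuperset(alt) or not _BASES.issuperset(rec.ref):
                    continue  # symbolic / spanning-deletion alleles
                in_tumor = ai in tum_alleles
                in_germline = ai in ger_alleles
                if not in_tumor and not in_germline:
                    continue
                hap = None
                if phased and in_tumor:
                    gt = tum.get("GT")
                    hits = [i for i, a in enumerate(gt) if a == ai]
                    if len(hits) == 1:
                        hap = hits[0]
                pos, ref, alt_n = normalize(rec.pos, rec.ref, alt)
                out.append(
                    CallerVariant(
                        caller_id=caller_id,
                        chrom=rec.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt_n,
                        in_tumor=in_tumor,
                        in_germline=in_germline,
                        phase_set=ps if phased else None,
                        haplotype=hap,
                    )
                )
        return out


def merge_callsets(callsets: Sequence[Iterable[CallerVariant]]) -> list[ConsensusVariant]:
    """Union-merge per-caller calls with majority-rule conflict resolution.

    At each (chrom, pos): identical (ref, alt) calls accumulate supporters.
    When callers disagree on (ref, alt), an allele is kept iff its supporters
    form a strict majority of the distinct callers reporting at that
    coordinate; if no allele reaches a strict majority the coordinate is
    rejected entirely.
    """
    by_pos: dict[tuple, list[CallerVariant]] = defaultdict(list)
    for calls in callsets:
        for cv in calls:
            by_pos[(cv.chrom, cv.pos)].append(cv)

    merged: list[ConsensusVariant] = []
    for (chrom, pos), calls in by_pos.items():
        reporting = {c.caller_id for c in calls}
        by_allele: dict[tuple, list[CallerVariant]] = defaultdict(list)
        for c in calls:
            by_allele[(c.ref, c.alt)].append(c)
        if len(by_allele) > 1:
            refs = {r for r, _ in by_allele}
            if len(refs) > 1:
                warnings.warn(
                    f"inconsistent ref alleles at {chrom}:{pos} ({sorted(refs)}); "
                    "treated as conflicting calls",
                    stacklevel=2,
                )
        for (ref, alt), group in by_allele.items():
            supporters = frozenset(c.caller_id for c in group)
            if len(by_allele) > 1 and not len(supporters) * 2 > len(reporting):
                if len(supporters) * 2 == len(reporting):
                    log.info("rejecting %s:%s %s>%s: no strict majority", chrom, pos, ref, alt)
                continue
            phase = next(
                ((c.phase_set, c.haplotype) for c in group if c.phase_set is not None),
                (None, None),
            )
            merged.append(
                ConsensusVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    supporters=supporters,
                    in_tumor=any(c.in_tumor for c in group),
                    in_germline=any(c.in_germline for c in group),
                    phase_set=phase[0],
                    haplotype=phase[1],
                )
            )
    merged.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return merged


def classify_origin(v: ConsensusVariant) -> str:
    """Somatic iff tumor-only; any germline evidence wins for germline status."""
    if v.in_germline:
        v.origin = GERMLINE_SNP
        if not v.in_tumor:
            warnings.warn(
                f"{v.variant_id}: germline-only call; not a vaccine target "
                "(linked-SNP candidate only if phased)",
                stacklevel=2,
            )
    elif v.in_tumor:
        v.origin = SOMATIC
    else:  # pragma: no cover - parser never emits absent/absent
        raise ValueError(f"{v.variant_id}: no tumor or germline presence recorded")
    return v.origin


def _supports_high_confidence(v: ConsensusVariant) -> bool:
    return "mutect" in v.supporters or len(v.supporters) >= 2


def link_phased_snps(variants: list[ConsensusVariant]) -> list[ConsensusVariant]:
    """Attach germline SNPs sharing phase set AND haplotype to somatic variants.

    Unphased variants are never linked (missing phase information leaves
    ``linked_snps`` empty).
    """
    snps_by_phase: dict[tuple, list[ConsensusVariant]] = defaultdict(list)
    for v in variants:
        if v.origin == GERMLINE_SNP and v.phase_set is not None and v.haplotype is not None:
            snps_by_phase[(v.chrom, v.phase_set, v.haplotype)].append(v)
    for v in variants:
        if v.origin != SOMATIC:
            continue
        v.linked_snps = []
        if v.phase_set is None or v.haplotype is None:
            continue
        v.linked_snps = [
            s
            for s in snps_by_phase.get((v.chrom, v.phase_set, v.haplotype), [])
            if s.key != v.key
        ]
    return variants


def select_high_confidence(variants: list[ConsensusVariant]) -> list[ConsensusVariant]:
    """Retain somatic variants called by MuTect alone or by >= 2 callers,
    plus germline SNPs phase-linked to a retained somatic variant.

    Linked SNPs inherit retention from their somatic partner; the caller
    support rule is not applied to them independently.
    """
    retained: list[ConsensusVariant] = []
    linked_seen: dict[tuple, ConsensusVariant] = {}
    for v in variants:
        if v.origin == SOMATIC and _supports_high_confidence(v):
            v.high_confidence = True
            retained.append(v)
            for s in v.linked_snps:
                linked_seen.setdefault(s.key, s)
    for s in linked_seen.values():
        s.high_confidence = True
        retained.append(s)
    retained.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return retained


def write_variant_table(variants: Iterable[ConsensusVariant], path: str | Path) -> None:
    """Write the merged annotated variant table (TSV, 1-based positions)."""
    cols = ["chrom", "pos", "ref", "alt", "supporters", "origin", "high_confidence", "phase_set"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        ",".join(sorted(v.supporters)),
                        v.origin or "",
                        str(v.high_confidence).lower(),
                        v.phase_set or "",
                    ]
                )
                + "\n"
            )
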