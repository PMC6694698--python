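"""Optimal long-peptide design, ranking and the tabular report.

For each surviving mutation the designer picks, over all contiguous windows
of the mutant context, the window containing the largest number of fully
contained predicted binders; among maxima the shortest, then the leftmost.
Designs are ranked by the minimum p-value of the contained class I binders,
then by total binder count, represented-allele count, an exact
ligand-database match as tie-break, and finally genomic coordinate; the top
N (default 10) make the report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from neopept.annotate import MutantContext
from neopept.binding import CandidatePeptide
from neopept.prioritize import HotspotOverlap, NONE

log = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "Rank",
    "Chromosome_position",
    "Gene",
    "Expression_TPM_p90",
    "Mutation",
    "Driver_status",
    "Long_peptide_sequence",
    "ipMSDB_HLA-I",
    "ipMSDB_HLA-II",
    "Lowest_HLA-I_pval",
    "Lowest_HLA-II_pval",
    "N_predicted_peptides",
    "N_HLA-I_alleles",
    "N_HLA-II_alleles",
]


@dataclass
class LongPeptideDesign:
    """The minimal contiguous context window maximizing contained binders."""

    mutation_id: str
    sequence: str
    start: int                      # 1-based inclusive, in context
    end: int
    n_binders_i: int = 0
    n_binders_ii: int = 0
    n_alleles_i: int = 0
    n_alleles_ii: int = 0
    min_pval_i: float | None = None
    min_pval_ii: float | None = None
    n_unique_peptides: int = 0      # unique binder sequences, classes pooled
    ipmsdb_i: str = NONE
    ipmsdb_ii: str = NONE
    rank: int | None = None
    contained: list = field(default_factory=list)
    # annotation pass-through, set by the pipeline
    chrom: str = ""
    pos: int = 0
    gene_symbol: str = ""
    mutation_label: str = ""
    expression_p90: float | None = None
    driver_status: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def total_binders(self) -> int:
        return self.n_binders_i + self.n_binders_ii


def design_long_peptide(
    ctx: MutantContext,
    binders: Sequence[CandidatePeptide],
    cutoff: float = 5.0,
    strict: bool = True,
    max_length: int | None = None,
) -> LongPeptideDesign | None:
    """Choose the window maximizing fully contained binders; shortest, then
    leftmost, among maxima.  Returns None with zero binders (the mutation
    then carries no design and is excluded from ranking).

    There is no length cap beyond the context itself by default; for long
    frameshift contexts *max_length* restricts the window (e.g. to a
    synthesizable peptide length), which can force the optimizer to pick the
    larger of two distant binder clusters.
    """
    binders = [b for b in binders if b.is_predicted_binder]
    if not binders:
        return None
    L = len(ctx.mutant_sequence)
    starts = np.array([b.span[0] for b in binders])
    ends = np.array([b.span[1] for b in binders])
    # counts[i, j] = number of spans fully inside window (i+1, j+1)
    pos = np.arange(1, L + 1)
    starts_ok = (pos[:, None] <= starts[None, :]).astype(np.int64)   # (L, B)
    ends_ok = (ends[None, :] <= pos[:, None]).astype(np.int64)       # (L, B)
    counts = starts_ok @ ends_ok.T
    ai, bi = np.meshgrid(pos, pos, indexing="ij")
    valid = bi >= ai
    if max_length is not None:
        valid &= (bi - ai + 1) <= max_length
    counts = np.where(valid, counts, -1)
    best_count = counts.max()
    ii, jj = np.nonzero(counts == best_count)
    lengths = jj - ii + 1
    k = np.lexsort((ii, lengths))[0]        # shortest, then leftmost
    a, b = int(ii[k] + 1), int(jj[k] + 1)
    contained = [x for x in binders if a <= x.span[0] and x.span[1] <= b]
    des = LongPeptideDesign(
        mutation_id=ctx.mutation_id,
        sequence=ctx.mutant_sequence[a - 1 : b],
        start=a,
        end=b,
        contained=contained,
    )
    alleles_i, alleles_ii = set(), set()
    pvals_i, pvals_ii = [], []
    uniq = set()
    for c in contained:
        uniq.add(c.sequence)
        passing = c.binding_alleles(cutoff, strict)
        p = c.min_p_value()
        if c.hla_class == "I":
            des.n_binders_i += 1
            alleles_i.update(passing)
            if p is not None:
                pvals_i.append(p)
        else:
            des.n_binders_ii += 1
            alleles_ii.update(passing)
            if p is not None:
                pvals_ii.append(p)
    des.n_alleles_i = len(alleles_i)
    des.n_alleles_ii = len(alleles_ii)
    des.min_pval_i = min(pvals_i) if pvals_i else None
    des.min_pval_ii = min(pvals_ii) if pvals_ii else None
    des.n_unique_peptides = len(uniq)
    return des


def _chrom_key(chrom: str) -> tuple:
    c = chrom.removeprefix("chr")
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, c)


def rank_designs(designs: Sequence[LongPeptideDesign]) -> list[LongPeptideDesign]:
    """Total order: min class I p-value ascending, total binders descending,
    represented alleles descending, exact DB match first, genomic coordinate
    ascending (final deterministic tie-break)."""
    def key(d: LongPeptideDesign):
        return (
            d.min_pval_i if d.min_pval_i is not None else float("inf"),
            -d.total_binders,
            -(d.n_alleles_i + d.n_alleles_ii),
            0 if EXACT_MATCH(d) else 1,
            _chrom_key(d.chrom),
            d.pos,
        )

    out = sorted(designs, key=key)
    for i, d in enumerate(out, start=1):
        d.rank = i
    return out


def EXACT_MATCH(d: LongPeptideDesign) -> bool:
    return "EXACT" in (d.ipmsdb_i, d.ipmsdb_ii)


def select_top(designs: Sequence[LongPeptideDesign], n: int = 10) -> list[LongPeptideDesign]:
    """First *n* designs by rank (all of them, with a warning, if fewer)."""
    designs = sorted(designs, key=lambda d: d.rank if d.rank is not None else 1 << 30)
    if len(designs) < n:
        warnings.warn(f"only {len(designs)} designs available for top {n}", stacklevel=2)
    return list(designs[:n])


def _fmt(x, nd=5) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return format(round(x, nd), "g")
    return str(x)


def build_report(designs: Sequence[LongPeptideDesign]) -> pd.DataFrame:
    """One row per design, columns mirroring the published report layout.

    Overlap categories of NONE print as empty strings; byte-identical on
    re-runs over the same inputs.
    """
    rows = []
    for d in designs:
        rows.append(
            {
                "Rank": d.rank,
                "Chromosome_position": f"{d.chrom.removeprefix('chr')}_{d.pos}",
                "Gene": d.gene_symbol,
                "Expression_TPM_p90": _fmt(d.expression_p90, 3),
                "Mutation": d.mutation_label,
                "Driver_status": d.driver_status,
                "Long_peptide_sequence": d.sequence,
                "ipMSDB_HLA-I": "" if d.ipmsdb_i == NONE else d.ipmsdb_i,
                "ipMSDB_HLA-II": "" if d.ipmsdb_ii == NONE else d.ipmsdb_ii,
                "Lowest_HLA-I_pval": _fmt(d.min_pval_i),
                "Lowest_HLA-II_pval": _fmt(d.min_pval_ii),
                "N_predicted_peptides": d.n_unique_peptides,
                "N_HLA-I_alleles": d.n_alleles_i,
                "N_HLA-II_alleles": d.n_alleles_ii,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
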