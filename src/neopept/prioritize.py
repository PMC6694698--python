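"""Exclusion filters and ligand-database hotspot overlap.

Mutations are excluded when their gene is not expressed in the target tissue
(90th-percentile TPM below 1), when they fall in hypermutated genes (likely
false positives), or — if enabled — when their source protein is
underrepresented in the ligand database.  Individual mutant peptides whose
exact sequence occurs anywhere in a reference proteome are removed
(wild-type identity filter).  HLA ligands cluster in presentation hotspots
along proteins; the overlap of the wild-type forms of a mutation's
candidates with database ligands is classified EXACT > INCLUDED > PARTIAL >
NONE per HLA class, and an EXACT match promotes the mutation as a ranking
tie-break (never a filter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from neopept.annotate import MutantContext
from neopept.binding import CandidatePeptide

log = logging.getLogger(__name__)

EXACT = "EXACT"
INCLUDED = "INCLUDED"
PARTIAL = "PARTIAL"
NONE = "NONE"

_ORDER = {EXACT: 3, INCLUDED: 2, PARTIAL: 1, NONE: 0}


@dataclass
class HotspotOverlap:
    """Best ligand-database overlap category per HLA class for one mutation."""

    class_i: str = NONE
    class_ii: str = NONE
    source_protein_coverage: float = 0.0

    def category(self, hla_class: str) -> str:
        return self.class_i if hla_class == "I" else self.class_ii

    @property
    def any_exact(self) -> bool:
        return EXACT in (self.class_i, self.class_ii)


class LigandDatabase:
    """Observed HLA-I/II ligands with source proteins and observation counts.

    Backed by a TSV with columns peptide, hla_class, protein, n_observations.
    """

    def __init__(self, records: pd.DataFrame):
        required = {"peptide", "hla_class", "protein", "n_observations"}
        if not required <= set(records.columns):
            raise ValueError(f"ligand DB needs columns {sorted(required)}")
        self.records = records.copy()
        self.records["hla_class"] = self.records["hla_class"].astype(str)
        self._exact = {
            cls: set(grp["peptide"])
            for cls, grp in self.records.groupby("hla_class")
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LigandDatabase":
        return cls(pd.read_csv(path, sep="\t"))

    def exact(self, peptide: str, hla_class: str) -> bool:
        return peptide in self._exact.get(hla_class, set())

    def ligands(self, hla_class: str | None = None) -> pd.DataFrame:
        if hla_class is None:
            return self.records
        return self.records[self.records["hla_class"] == hla_class]

    def protein_ligands(self, protein: str, hla_class: str | None = None) -> list[str]:
        df = self.ligands(hla_class)
        return list(df.loc[df["protein"] == protein, "peptide"])

    def protein_coverage(self, protein: str, protein_seq: str) -> float:
        """Fraction of protein residues covered by >= 1 database ligand."""
        if not protein_seq:
            return 0.0
        covered = np.zeros(len(protein_seq), dtype=bool)
        for lig in self.protein_ligands(protein):
            start = protein_seq.find(lig)
            while start >= 0:
                covered[start : start + len(lig)] = True
                start = protein_seq.find(lig, start + 1)
        return float(covered.mean())


def p90_tpm(samples: Sequence[float], percentile: float = 90.0) -> float:
    """90th-percentile TPM with linear interpolation between order statistics."""
    return float(np.percentile(np.asarray(samples, dtype=float), percentile,
                               method="linear"))


def gene_p90_table(
    expression: pd.DataFrame,
    tissue: str,
    percentile: float = 90.0,
) -> dict[str, float]:
    """Per-gene 90th-percentile TPM for one tissue.

    The table carries either a precomputed ``p90_tpm`` column or one numeric
    column per sample.
    """
    if "tissue" in expression.columns:
        sub = expression[expression["tissue"] == tissue]
        if sub.empty:
            raise ValueError(f"tissue {tissue!r} absent from expression table")
    else:
        sub = expression
    out: dict[str, float] = {}
    if "p90_tpm" in sub.columns:
        for r in sub.itertuples():
            out[r.gene] = float(r.p90_tpm)
        return out
    sample_cols = [
        c for c in sub.columns
        if c not in ("gene", "tissue") and pd.api.types.is_numeric_dtype(sub[c])
    ]
    if not sample_cols:
        raise ValueError("expression table has neither p90_tpm nor sample columns")
    for _, row in sub.iterrows():
        out[row["gene"]] = p90_tpm(row[sample_cols].to_numpy(dtype=float), percentile)
    return out


def filter_expression(
    mutations: Sequence,
    expression: pd.DataFrame,
    tissue: str,
    threshold: float = 1.0,
    percentile: float = 90.0,
) -> tuple[list, list]:
    """Drop mutations whose gene's p90 TPM is strictly below *threshold*.

    Genes absent from the table are retained with a missing-expression flag
    (``expression_p90`` stays None).  Returns (retained, dropped); retained
    mutations carry the p90 value for the report.
    """
    p90 = gene_p90_table(expression, tissue, percentile)
    kept, dropped = [], []
    for m in mutations:
        val = p90.get(m.gene_symbol)
        m.expression_p90 = val
        if val is not None and val < threshold:
            m.filtered_by = "expression"
            dropped.append(m)
        else:
            if val is None:
                log.warning("gene %s missing from expression table; retained with flag",
                            m.gene_symbol)
            kept.append(m)
    return kept, dropped


def filter_wt_identity(
    candidates: Sequence[CandidatePeptide],
    reference_proteins: Iterable[str],
) -> tuple[list, list]:
    """Remove mutant peptides occurring verbatim in any reference proteome.

    Only the mutant sequence matters; the wild-type counterpart being present
    (as it normally is) never removes a candidate.
    """
    blob = "|".join(reference_proteins)
    kept, removed = [], []
    for c in candidates:
        (removed if c.sequence in blob else kept).append(c)
    return kept, removed


def filter_hypermutated(
    mutations: Sequence,
    max_per_gene: int | float = 3,
) -> tuple[list, list]:
    """Drop all mutations in genes with more than *max_per_gene* somatic
    mutations (likely false positives)."""
    counts: dict[str, int] = {}
    for m in mutations:
        counts[m.gene_symbol] = counts.get(m.gene_symbol, 0) + 1
    kept, dropped = [], []
    for m in mutations:
        if counts[m.gene_symbol] > max_per_gene:
            m.filtered_by = "hypermutated"
            dropped.append(m)
        else:
            kept.append(m)
    return kept, dropped


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def classify_ipmsdb_overlap(
    ctx: MutantContext,
    candidates: Sequence[CandidatePeptide],
    db: LigandDatabase,
    protein_id: str,
    protein_seq: str,
    min_partial_overlap: int = 5,
) -> HotspotOverlap:
    """Best overlap of the wild-type forms of a mutation's candidates with
    database ligands, per HLA class.

    EXACT: a WT form equals a ligand.  INCLUDED: a WT form is a proper
    substring of a ligand or properly contains one.  PARTIAL: a WT form
    overlaps a ligand mapped to the same protein by at least
    *min_partial_overlap* residues.  Otherwise NONE.
    """
    result = HotspotOverlap(
        source_protein_coverage=db.protein_coverage(protein_id, protein_seq)
    )
    for hla_class, attr in (("I", "class_i"), ("II", "class_ii")):
        wt_forms = sorted({c.wt_sequence for c in candidates if c.hla_class == hla_class})
        if not wt_forms:
            continue
        ligands = list(db.ligands(hla_class)["peptide"])
        best = NONE
        if any(db.exact(wt, hla_class) for wt in wt_forms):
            best = EXACT
        elif any(
            (wt in lig or lig in wt) and wt != lig
            for wt in wt_forms
            for lig in ligands
        ):
            best = INCLUDED
        else:
            # same-protein positional overlap
            own = []
            for lig in db.protein_ligands(protein_id, hla_class):
                s = protein_seq.find(lig)
                while s >= 0:
                    own.append((s + 1, s + len(lig)))       # 1-based in protein
                    s = protein_seq.find(lig, s + 1)
            for c in candidates:
                if c.hla_class != hla_class:
                    continue
                start = ctx.protein_start + c.context_start - 1
                span = (start, start + c.length - 1)
                if any(_spans_overlap(span, ls) >= min_partial_overlap for ls in own):
                    best = PARTIAL
                    break
        setattr(result, attr, best)
    return result


def filter_underrepresented(
    mutations: Sequence,
    db: LigandDatabase,
    protein_seqs: dict[str, str],
    threshold: float = 0.0,
) -> tuple[list, list]:
    """Drop mutations whose source protein's ligand-database coverage is
    below *threshold* (default 0: filter inert unless enabled)."""
    kept, dropped = [], []
    for m in mutations:
        cov = db.protein_coverage(m.transcript_id, protein_seqs.get(m.transcript_id, ""))
        m.db_coverage = cov
        if threshold > 0 and cov < threshold:
            m.filtered_by = "underrepresented"
            dropped.append(m)
        else:
            kept.append(m)
    return kept, dropped
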