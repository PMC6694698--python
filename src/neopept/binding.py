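"""Candidate epitope enumeration and per-allele binding scores.

Candidates are all class I (9–12-mer) / class II (12–19-mer) windows of a
mutant context whose span covers the somatic residue.  Scores come either
from an external predictor's score table (adapter) or from the built-in
position-weight-matrix scorer: a class I peptide scores the sum of per-
position weights for its length-matched matrix; a class II peptide scores
the best 9-mer core under a single core matrix.  Raw scores are converted
to percentile ranks against a seeded decoy distribution of random peptides
(%Rank = percentage of decoys scoring at least as high); the associated
p-value is %Rank/100.  A candidate is a predicted binder when %Rank is below
the cutoff (default 5, strict) for at least one allele, or when its
wild-type form is an exact ligand-database match.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from neopept.annotate import MutantContext
from neopept.config import ConfigurationError

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

HLA_I_LENGTHS = (9, 10, 11, 12)
HLA_II_LENGTHS = (12, 13, 14, 15, 16, 17, 18, 19)
CORE_LEN = 9


@dataclass
class AlleleScore:
    score: float
    percent_rank: float      # 0–100
    p_value: float           # percent_rank / 100 for the built-in scorer


@dataclass
class CandidatePeptide:
    """A mutation-spanning window of a mutant context."""

    sequence: str
    wt_sequence: str
    hla_class: str                      # "I" or "II"
    context_start: int                  # 1-based index in the context
    covers_mutation: bool = True
    scores: dict = field(default_factory=dict)   # allele -> AlleleScore
    unscored: bool = False
    is_predicted_binder: bool | None = None
    db_match: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive (start, end) in the context."""
        return (self.context_start, self.context_start + self.length - 1)

    def best_percent_rank(self) -> float | None:
        if not self.scores:
            return None
        return min(s.percent_rank for s in self.scores.values())

    def min_p_value(self) -> float | None:
        if not self.scores:
            return None
        return min(s.p_value for s in self.scores.values())

    def binding_alleles(self, cutoff: float = 5.0, strict: bool = True) -> list[str]:
        ok = (lambda r: r < cutoff) if strict else (lambda r: r <= cutoff)
        return sorted(a for a, s in self.scores.items() if ok(s.percent_rank))


def enumerate_candidates(
    ctx: MutantContext,
    hla_class: str,
    lengths: Sequence[int] | None = None,
    include_linked: bool = False,
) -> list[CandidatePeptide]:
    """All windows of the allowed lengths spanning the mutated residue.

    With ``include_linked`` windows covering only a linked-SNP edit are also
    emitted (off by default: candidates must span the somatic residue).
    """
    if hla_class not in ("I", "II"):
        raise ValueError(f"hla_class must be 'I' or 'II', got {hla_class!r}")
    if lengths is None:
        lengths = HLA_I_LENGTHS if hla_class == "I" else HLA_II_LENGTHS
    L = len(ctx.mutant_sequence)
    if L < min(lengths):
        warnings.warn(
            f"{ctx.mutation_id}: context length {L} below class {hla_class} minimum",
            stacklevel=2,
        )
        return []
    cover = {ctx.mutated_index}
    if include_linked:
        cover.update(i for i, _, _ in ctx.applied_linked_edits)
    out: list[CandidatePeptide] = []
    for k in lengths:
        for start in range(1, L - k + 2):
            end = start + k - 1
            if any(start <= c <= end for c in cover):
                out.append(
                    CandidatePeptide(
                        sequence=ctx.mutant_sequence[start - 1 : end],
                        wt_sequence=ctx.wt_sequence[start - 1 : end],
                        hla_class=hla_class,
                        context_start=start,
                    )
                )
    return out


def _encode(peptides: np.ndarray | Sequence[str]) -> np.ndarray:
    """(n, k) residue-index matrix for equal-length peptides."""
    arr = np.array([[_AA_INDEX[a] for a in p] for p in peptides], dtype=np.int64)
    return arr


@dataclass
class PwmModel:
    """Per-allele position weight matrices plus decoy score distributions.

    Class I carries one (k, 20) matrix per supported peptide length; class II
    carries a single 9-position core matrix and scores a peptide by its best
    core.  Decoy distributions are sorted score arrays from N random
    length-matched peptides drawn i.i.d. from the background residue
    frequencies (uniform by default), generated from a caller-supplied seeded
    RNG so calibration is deterministic.
    """

    allele: str
    hla_class: str                               # "I" or "II"
    matrices: dict = field(default_factory=dict)  # length -> (k, 20) array (class I)
    core: np.ndarray | None = None                # (9, 20) array (class II)
    decoys: dict = field(default_factory=dict)    # length -> sorted scores

    def supported_lengths(self, lengths: Sequence[int]) -> list[int]:
        if self.hla_class == "I":
            return [k for k in lengths if k in self.matrices]
        return [k for k in lengths if k >= CORE_LEN]

    # -- scoring -----------------------------------------------------------

    def score(self, peptide: str) -> float:
        if not set(peptide) <= set(AMINO_ACIDS):
            raise ValueError(f"non-standard residue in {peptide!r}")
        if self.hla_class == "I":
            if len(peptide) not in self.matrices:
                raise ConfigurationError(
                    f"{self.allele}: no matrix for length {len(peptide)}"
                )
            m = self.matrices[len(peptide)]
            idx = [_AA_INDEX[a] for a in peptide]
            return float(m[np.arange(len(peptide)), idx].sum())
        if len(peptide) < CORE_LEN:
            raise ConfigurationError(f"{self.allele}: class II peptide shorter than core")
        return float(self._core_scores_matrix(_encode([peptide])).max())

    def _score_matrix_i(self, enc: np.ndarray, k: int) -> np.ndarray:
        m = self.matrices[k]
        return m[np.arange(k)[None, :], enc].sum(axis=1)

    def _core_scores_matrix(self, enc: np.ndarray) -> np.ndarray:
        """(n, k) encoded peptides -> (n, k-8) per-core sums under the core PWM."""
        n, k = enc.shape
        ncores = k - CORE_LEN + 1
        out = np.empty((n, ncores))
        pos = np.arange(CORE_LEN)
        for c in range(ncores):
            out[:, c] = self.core[pos[None, :], enc[:, c : c + CORE_LEN]].sum(axis=1)
        return out

    # -- decoy calibration -------------------------------------------------

    def generate_decoys(self, rng: np.random.Generator, n: int,
                        lengths: Sequence[int]) -> None:
        """Draw n random peptides per length and store the sorted scores."""
        for k in self.supported_lengths(lengths):
            enc = rng.integers(0, 20, size=(n, k))
            if self.hla_class == "I":
                scores = self._score_matrix_i(enc, k)
            else:
                scores = self._core_scores_matrix(enc).max(axis=1)
            self.decoys[k] = np.sort(scores)

    # -- serialization (per-allele TSV: length, pos, then one column per AA)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        if self.hla_class == "I":
            for k in sorted(self.matrices):
                for p in range(k):
                    rows.append([k, p + 1, *self.matrices[k][p]])
        else:
            for p in range(CORE_LEN):
                rows.append([CORE_LEN, p + 1, *self.core[p]])
        df = pd.DataFrame(rows, columns=["length", "pos", *AMINO_ACIDS])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, allele: str, hla_class: str) -> "PwmModel":
        df = pd.read_csv(path, sep="\t")
        model = cls(allele=allele, hla_class=hla_class)
        aas = list(AMINO_ACIDS)
        if hla_class == "I":
            for k, grp in df.groupby("length"):
                grp = grp.sort_values("pos")
                model.matrices[int(k)] = grp[aas].to_numpy(dtype=float)
        else:
            grp = df.sort_values("pos")
            model.core = grp[aas].to_numpy(dtype=float)
        return model


def calibrate_percent_rank(score: float, m: PwmModel, length: int) -> tuple[float, float]:
    """(%Rank, p-value) of *score* against the allele's decoy distribution.

    %Rank = 100 x fraction of decoys scoring >= score; p = %Rank/100.
    """
    d = m.decoys.get(length)
    if d is None or len(d) == 0:
        raise ConfigurationError(f"{m.allele}: no decoy distribution for length {length}")
    n_ge = len(d) - np.searchsorted(d, score, side="left")
    pr = 100.0 * n_ge / len(d)
    return float(pr), float(pr) / 100.0


def score_candidates(
    candidates: list[CandidatePeptide],
    models: Sequence[PwmModel],
) -> list[CandidatePeptide]:
    """Score every candidate against every class-matched PWM model.

    Candidates with non-standard residues are dropped with a warning; returns
    the scored (retained) list.
    """
    kept: list[CandidatePeptide] = []
    aa_ok = frozenset(AMINO_ACIDS)
    for c in candidates:
        if not aa_ok.issuperset(c.sequence):
            warnings.warn(f"dropping {c.sequence!r}: non-standard residue", stacklevel=2)
            continue
        for m in models:
            if m.hla_class != c.hla_class:
                continue
            if m.hla_class == "I" and c.length not in m.matrices:
                continue
            s = m.score(c.sequence)
            pr, p = calibrate_percent_rank(s, m, c.length)
            c.scores[m.allele] = AlleleScore(score=s, percent_rank=pr, p_value=p)
        if not c.scores:
            c.unscored = True
        kept.append(c)
    return kept


def load_external_scores(
    path: str | Path,
    candidates: list[CandidatePeptide],
) -> list[CandidatePeptide]:
    """Attach a published predictor's scores from a TSV.

    Required columns: peptide, allele, score, percent_rank; p_value optional
    (defaulted to percent_rank/100).  Candidates with no row for any allele
    are flagged unscored and excluded from binder calls.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "score", "percent_rank"}
    if not required <= set(df.columns):
        raise ConfigurationError(
            f"{path}: external score table needs columns {sorted(required)}"
        )
    if "p_value" not in df.columns:
        df["p_value"] = df["percent_rank"] / 100.0
    dup = df.groupby(["peptide", "allele"]).nunique()
    conflicts = dup[(dup[["score", "percent_rank", "p_value"]] > 1).any(axis=1)]
    if len(conflicts):
        raise ConfigurationError(
            f"{path}: conflicting duplicate rows for {list(conflicts.index[:3])}"
        )
    df = df.drop_duplicates(subset=["peptide", "allele"])
    table = {
        (r.peptide, r.allele): AlleleScore(float(r.score), float(r.percent_rank), float(r.p_value))
        for r in df.itertuples()
    }
    alleles = sorted(df["allele"].unique())
    for c in candidates:
        for a in alleles:
            rec = table.get((c.sequence, a))
            if rec is not None:
                c.scores[a] = rec
        if not c.scores:
            c.unscored = True
            log.warning("candidate %s has no external score; excluded from binder calls",
                        c.sequence)
    return candidates


def call_binders(
    candidates: Iterable[CandidatePeptide],
    ligand_db=None,
    cutoff: float = 5.0,
    strict: bool = True,
) -> list[CandidatePeptide]:
    """Set ``is_predicted_binder``: %Rank below cutoff for >= 1 allele, or the
    wild-type form is an exact ligand-database match."""
    out = []
    for c in candidates:
        predicted = (not c.unscored) and bool(c.binding_alleles(cutoff, strict))
        c.db_match = bool(ligand_db is not None and ligand_db.exact(c.wt_sequence, c.hla_class))
        c.is_predicted_binder = predicted or c.db_match
        out.append(c)
    return out
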