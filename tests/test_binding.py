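"""Candidate enumeration, PWM scoring, decoy calibration, external score
tables and binder calling."""

import numpy as np
import pandas as pd
import pytest

from neopept.annotate import MutantContext
from neopept.binding import (
    AMINO_ACIDS,
    AlleleScore,
    CandidatePeptide,
    PwmModel,
    calibrate_percent_rank,
    call_binders,
    enumerate_candidates,
    load_external_scores,
    score_candidates,
)
from neopept.config import ConfigurationError
from neopept.prioritize import LigandDatabase


def ctx_of(seq, idx=16, wt=None, edits=()):
    return MutantContext(
        mutation_id="m1", gene_symbol="G", transcript_id="T",
        mutant_sequence=seq, wt_sequence=wt or seq, mutated_index=idx,
        protein_start=1, applied_linked_edits=list(edits),
    )


def brute_force_windows(L, idx, lengths):
    """Independent oracle: all (start, k) spans containing position idx."""
    out = []
    for k in lengths:
        for s in range(1, L - k + 2):
            if s <= idx <= s + k - 1:
                out.append((s, k))
    return out


# ---------------------------------------------------------------------------
# enumeration


@pytest.mark.parametrize(
    "L,idx,cls,lengths,expected",
    [
        (31, 16, "I", (9, 10, 11, 12), 42),
        # for k >= 17 the 31-mer clips the start range to 31-k+1, so the
        # count is 12+13+14+15+16+15+14+13, not the unclipped sum of k
        (31, 16, "II", tuple(range(12, 20)), 112),
        (9, 5, "I", (9, 10, 11, 12), 1),
    ],
)
def test_enumeration_counts_match_oracle(L, idx, cls, lengths, expected):
    seq = (AMINO_ACIDS * 3)[:L]
    cands = enumerate_candidates(ctx_of(seq, idx), cls)
    assert len(cands) == len(brute_force_windows(L, idx, lengths)) == expected
    assert all(c.span[0] <= idx <= c.span[1] for c in cands)


def test_enumeration_random_contexts_match_oracle():
    rng = np.random.default_rng(4)
    for _ in range(30):
        L = int(rng.integers(9, 32))
        idx = int(rng.integers(1, L + 1))
        seq = "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, L)])
        got = {(c.span[0], c.length) for c in enumerate_candidates(ctx_of(seq, idx), "I")}
        assert got == set(brute_force_windows(L, idx, (9, 10, 11, 12)))


def test_context_below_minimum_warns_empty():
    with pytest.warns(UserWarning, match="below class"):
        assert enumerate_candidates(ctx_of("ACDEFGHK", 4), "I") == []


def test_linked_only_windows_off_by_default():
    seq = (AMINO_ACIDS * 2)[:31]
    base = enumerate_candidates(ctx_of(seq, 16), "I")
    with_linked = enumerate_candidates(ctx_of(seq, 16, edits=[(2, "A", "C")]), "I",
                                       include_linked=True)
    assert len(with_linked) > len(base)


# ---------------------------------------------------------------------------
# PWM scoring


def uniform_model(allele="X", cls="I", w=0.05):
    m = PwmModel(allele=allele, hla_class=cls)
    if cls == "I":
        for k in (9, 10, 11, 12):
            m.matrices[k] = np.full((k, 20), w)
    else:
        m.core = np.full((9, 20), w)
    return m


def test_uniform_matrix_scores_identical():
    m = uniform_model()
    assert m.score("A" * 9) == pytest.approx(m.score("W" * 9))


def test_anchor_weight_scoring():
    m = uniform_model(w=0.0)
    m.matrices[9][0, AMINO_ACIDS.index("A")] = 1.0
    assert m.score("A" + "C" * 8) == pytest.approx(1.0)
    assert m.score("C" * 9) == pytest.approx(0.0)


def test_class_ii_takes_best_core():
    m = uniform_model(cls="II", w=0.0)
    m.core[0, AMINO_ACIDS.index("W")] = 2.0
    # 12-mer with W at offset 3: only the core starting there scores
    assert m.score("AAA" + "W" + "A" * 8) == pytest.approx(2.0)
    assert m.score("A" * 12) == pytest.approx(0.0)


def test_non_standard_residue_rejected():
    with pytest.raises(ValueError, match="non-standard"):
        uniform_model().score("AAAAAAAAX")


# ---------------------------------------------------------------------------
# decoy calibration


@pytest.fixture(scope="module")
def calibrated():
    m = uniform_model(allele="A1")
    m.matrices[9] = np.tile(np.linspace(0.0, 1.0, 20), (9, 1))
    m.generate_decoys(np.random.default_rng(0), 5000, (9,))
    return m


def test_score_above_all_decoys_rank_zero(calibrated):
    pr, p = calibrate_percent_rank(1e9, calibrated, 9)
    assert pr == 0.0 and p == 0.0


def test_score_at_median_rank_50(calibrated):
    med = float(np.median(calibrated.decoys[9]))
    pr, _ = calibrate_percent_rank(med, calibrated, 9)
    assert pr == pytest.approx(50.0, abs=2.0)


def test_calibration_deterministic():
    a, b = uniform_model("A1"), uniform_model("A1")
    for m in (a, b):
        m.matrices[9] = np.tile(np.linspace(0.0, 1.0, 20), (9, 1))
        m.generate_decoys(np.random.default_rng(123), 2000, (9,))
    assert np.array_equal(a.decoys[9], b.decoys[9])


def test_empty_decoys_error(calibrated):
    with pytest.raises(ConfigurationError, match="decoy"):
        calibrate_percent_rank(0.5, calibrated, 10)


def test_percent_rank_monotone_in_score(calibrated):
    scores = np.sort(np.random.default_rng(1).uniform(0, 9, 50))
    ranks = [calibrate_percent_rank(s, calibrated, 9)[0] for s in scores]
    assert all(r1 >= r2 for r1, r2 in zip(ranks, ranks[1:]))


def test_pwm_tsv_roundtrip(tmp_path, calibrated):
    calibrated.to_tsv(tmp_path / "a.tsv")
    back = PwmModel.from_tsv(tmp_path / "a.tsv", "A1", "I")
    assert np.allclose(back.matrices[9], calibrated.matrices[9])


# ---------------------------------------------------------------------------
# external scores + binder calls


def cands_of(seqs, cls="I"):
    return [CandidatePeptide(s, s.replace("W", "R"), cls, 1) for s in seqs]


def test_external_scores_full_coverage(tmp_path):
    cands = cands_of(["AAAAAAAAA", "CCCCCCCCC"])
    df = pd.DataFrame(
        {"peptide": ["AAAAAAAAA", "CCCCCCCCC"], "allele": ["A1", "A1"],
         "score": [1.0, 2.0], "percent_rank": [50.0, 1.0]}
    )
    path = tmp_path / "s.tsv"
    df.to_csv(path, sep="\t", index=False)
    out = load_external_scores(path, cands)
    assert not any(c.unscored for c in out)
    assert out[0].scores["A1"].p_value == pytest.approx(0.5)  # derived from %Rank


def test_external_scores_missing_peptide_flagged(tmp_path):
    cands = cands_of(["AAAAAAAAA", "CCCCCCCCC"])
    pd.DataFrame(
        {"peptide": ["AAAAAAAAA"], "allele": ["A1"], "score": [1.0], "percent_rank": [1.0]}
    ).to_csv(tmp_path / "s.tsv", sep="\t", index=False)
    out = load_external_scores(tmp_path / "s.tsv", cands)
    missing = next(c for c in out if c.sequence == "CCCCCCCCC")
    assert missing.unscored
    called = call_binders(out, cutoff=5.0)
    assert next(c for c in called if c.sequence == "CCCCCCCCC").is_predicted_binder is False


def test_external_scores_conflicting_duplicates_error(tmp_path):
    pd.DataFrame(
        {"peptide": ["AAAAAAAAA"] * 2, "allele": ["A1"] * 2,
         "score": [1.0, 2.0], "percent_rank": [1.0, 2.0]}
    ).to_csv(tmp_path / "s.tsv", sep="\t", index=False)
    with pytest.raises(ConfigurationError, match="conflicting"):
        load_external_scores(tmp_path / "s.tsv", cands_of(["AAAAAAAAA"]))


def with_rank(seq, rank, cls="I", wt=None):
    c = CandidatePeptide(seq, wt or seq, cls, 1)
    c.scores["A1"] = AlleleScore(0.0, rank, rank / 100)
    return c


def test_binder_cutoff_strict():
    a = with_rank("AAAAAAAAA", 4.9)
    b = with_rank("CCCCCCCCC", 5.1)
    e = with_rank("DDDDDDDDD", 5.0)
    called = call_binders([a, b, e], cutoff=5.0, strict=True)
    assert [c.is_predicted_binder for c in called] == [True, False, False]
    # config switch for "<="
    assert call_binders([with_rank("DDDDDDDDD", 5.0)], cutoff=5.0, strict=False)[0].is_predicted_binder


def test_db_exact_match_promotes_nonbinder():
    db = LigandDatabase(pd.DataFrame(
        {"peptide": ["RRRRRRRRR"], "hla_class": ["I"], "protein": ["P1"],
         "n_observations": [3]}
    ))
    weak = with_rank("KKKKKKKKK", 80.0, wt="RRRRRRRRR")
    assert call_binders([weak], db)[0].is_predicted_binder
    assert call_binders([weak], db)[0].db_match


def test_cutoff_extremes():
    cands = [with_rank("AAAAAAAAA", r) for r in (0.1, 42.0, 99.9)]
    assert all(c.is_predicted_binder for c in call_binders(cands, cutoff=100.0))
    assert not any(c.is_predicted_binder for c in call_binders(cands, cutoff=0.0))


def test_score_candidates_skips_unsupported_length():
    m = uniform_model()
    del m.matrices[12]
    m.generate_decoys(np.random.default_rng(0), 100, (9, 10, 11))
    cands = [CandidatePeptide("A" * 12, "A" * 12, "I", 1)]
    out = score_candidates(cands, [m])
    assert out[0].unscored
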