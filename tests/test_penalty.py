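"""Position/type-weighted penalty scoring and threshold classification."""

import numpy as np
import pandas as pd
import pytest

from primerval import iupac
from primerval.exceptions import PrimervalError
from primerval.model import DegeneratePrimer
from primerval.penalty import (
    FAILED,
    MISSING,
    WORKING,
    PenaltyMatrices,
    classification_table,
    classify,
    evaluate_penalties,
    pair_penalty,
    primer_penalty,
    score_distribution,
    uniform_matrices,
)

FLAT = uniform_matrices(mismatch=1.0, position=1.0)
DEFAULT = PenaltyMatrices.default()


class TestPairPenalty:
    def test_concrete_match_is_zero(self):
        assert pair_penalty("A", "A", FLAT) == 0.0

    def test_wobble_half_credit(self):
        # primer W = {A,T} vs template A: (A,A) matches, (T,A) mismatches
        expected = 0.5 * DEFAULT.type_factor[("T", "A")]
        assert pair_penalty("W", "A", DEFAULT) == pytest.approx(expected)

    def test_primer_n_three_quarter_credit(self):
        # primer N vs concrete base: 3 of 4 ordered pairs mismatch
        for base in "ACGT":
            mm = [DEFAULT.type_factor[(x, base)] for x in "ACGT" if x != base]
            assert pair_penalty("N", base, DEFAULT) == pytest.approx(0.75 * np.mean(mm))

    def test_template_gap_and_n_rows(self):
        assert pair_penalty("A", "-", DEFAULT) == DEFAULT.type_factor[("A", "-")]
        assert pair_penalty("A", "N", DEFAULT) == DEFAULT.type_factor[("A", "N")]

    def test_ambiguous_template_averages(self):
        # primer A vs template R={A,G}: mean of match and tf(A,G)
        expected = 0.5 * DEFAULT.type_factor[("A", "G")]
        assert pair_penalty("A", "R", DEFAULT) == pytest.approx(expected)


class TestPrimerPenalty:
    def test_perfect_match_scores_zero(self):
        p = DegeneratePrimer("p", "ACGTACGTACGTACGTACGT", "forward")
        score, missing = primer_penalty(p, p.sequence, DEFAULT)
        assert score == 0.0 and not missing

    def test_hand_computed_two_mismatch_score(self):
        # 20-mer, mismatches at positions 3 and 17 (1-based from 5')
        p = DegeneratePrimer("p", "A" * 20, "forward")
        site = list("A" * 20)
        site[2] = "G"   # distance from 3' = 18
        site[16] = "C"  # distance from 3' = 4
        expected = (
            DEFAULT.position(18) * DEFAULT.type_factor[("A", "G")]
            + DEFAULT.position(4) * DEFAULT.type_factor[("A", "C")]
        )
        score, _ = primer_penalty(p, "".join(site), DEFAULT)
        assert score == pytest.approx(expected)

    def test_three_prime_mismatch_costs_more_than_five_prime(self):
        p = DegeneratePrimer("p", "A" * 20, "forward")
        terminal = "A" * 19 + "G"
        five_prime = "G" + "A" * 19
        s3, _ = primer_penalty(p, terminal, DEFAULT)
        s5, _ = primer_penalty(p, five_prime, DEFAULT)
        assert s3 > s5

    def test_reverse_primer_distance_from_its_own_three_prime(self):
        rev = DegeneratePrimer("r", "A" * 10, "reverse")
        plus = iupac.reverse_complement(rev.sequence)  # TTTTTTTTTT
        # plus-strand 5' base corresponds to the reverse primer's 3' terminus
        mutated = "C" + plus[1:]
        score, _ = primer_penalty(rev, mutated, DEFAULT)
        assert score == pytest.approx(DEFAULT.position(1) * DEFAULT.type_factor[("A", "G")])

    def test_adjacency_invariance_at_factor_one(self):
        p = DegeneratePrimer("p", "A" * 12, "forward")
        adjacent = "GG" + "A" * 10
        spread = "G" + "A" * 5 + "G" + "A" * 5
        flat = uniform_matrices(mismatch=1.0, position=1.0)
        assert primer_penalty(p, adjacent, flat)[0] == primer_penalty(p, spread, flat)[0] == 2.0

    def test_adjacency_factor_above_one_penalises_runs(self):
        p = DegeneratePrimer("p", "A" * 12, "forward")
        adjacent = "GG" + "A" * 10
        spread = "G" + "A" * 5 + "G" + "A" * 5
        pen = uniform_matrices(mismatch=1.0, position=1.0, adjacency_factor=2.0)
        assert primer_penalty(p, adjacent, pen)[0] > primer_penalty(p, spread, pen)[0]

    def test_monotonic_in_added_mismatches(self):
        p = DegeneratePrimer("p", "ACGTACGTACGTACGTACGT", "forward")
        site = list(p.sequence)
        prev = 0.0
        for j in (0, 7, 13, 19):
            site[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[site[j]]
            score, _ = primer_penalty(p, "".join(site), DEFAULT)
            assert score > prev
            prev = score

    def test_missing_flags(self):
        p = DegeneratePrimer("p", "ACGT", "forward")
        assert primer_penalty(p, "----", DEFAULT)[1] is True  # truncated site
        assert primer_penalty(p, "AC-T", DEFAULT)[1] is False  # scored via gap row
        import dataclasses

        gapna = dataclasses.replace(DEFAULT, gap_as_missing=True)
        assert primer_penalty(p, "AC-T", gapna)[1] is True
        nna = dataclasses.replace(DEFAULT, n_as_missing=True)
        assert primer_penalty(p, "ACNT", nna)[1] is True


class TestClassification:
    def test_threshold_boundary_strictly_below(self):
        df = pd.DataFrame(
            {
                "sequence_id": ["a", "b", "c"],
                "species": ["s"] * 3,
                "taxon": ["t"] * 3,
                "forward_score": [18.45, 99.9, 75.0],
                "reverse_score": [120.4, 50.0, 75.0],
                "missing": [False, False, False],
            }
        )
        out = classify(df, threshold=150.0)
        assert out.loc[0, "combined"] == pytest.approx(138.85)
        assert out.loc[0, "classification"] == WORKING
        assert out.loc[1, "classification"] == WORKING
        assert out.loc[2, "classification"] == FAILED  # combined exactly 150

    def test_engineered_percentages(self):
        df = pd.DataFrame(
            {
                "sequence_id": [f"s{i}" for i in range(10)],
                "species": ["sp"] * 10,
                "taxon": ["t"] * 10,
                "forward_score": [50.0] * 5 + [100.0] * 3 + [np.nan] * 2,
                "reverse_score": [50.0] * 5 + [100.0] * 3 + [np.nan] * 2,
                "missing": [False] * 8 + [True] * 2,
            }
        )
        table = classification_table(classify(df, threshold=150.0))
        row = table.iloc[0]
        assert (row["working"], row["failed"], row["missing"]) == (5, 3, 2)
        assert (row["working_pct"], row["failed_pct"], row["missing_pct"]) == (50.0, 30.0, 20.0)

    def test_percentages_partition_every_taxon(self, scenario):
        truth, pairs, aln, _ = scenario
        results = evaluate_penalties(aln, pairs["AscCOI2"])
        table = classification_table(results)
        sums = table[["working_pct", "failed_pct", "missing_pct"]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=0.02)
        assert (table[["working", "failed", "missing"]].sum(axis=1) == table["total"]).all()

    def test_empty_input_rejected(self):
        with pytest.raises(PrimervalError):
            classify(pd.DataFrame())


def test_score_distribution_constant_scores():
    df = pd.DataFrame(
        {
            "taxon": ["t"] * 4,
            "forward_score": [7.0] * 4,
            "reverse_score": [3.0] * 4,
        }
    )
    agg = score_distribution(df)
    fwd = agg[agg["direction"] == "forward"].iloc[0]
    assert fwd["median"] == 7.0 and fwd["q1"] == fwd["q3"] == 7.0


def test_matrices_yaml_roundtrip(tmp_path):
    path = tmp_path / "m.yaml"
    DEFAULT.to_yaml(path)
    back = PenaltyMatrices.from_yaml(path)
    assert back.position_factor == DEFAULT.position_factor
    assert back.type_factor == DEFAULT.type_factor


def test_matrices_validation():
    with pytest.raises(ValueError, match="non-increasing"):
        PenaltyMatrices((1.0, 2.0), FLAT.type_factor)
    bad = dict(FLAT.type_factor)
    bad[("A", "A")] = 1.0
    with pytest.raises(ValueError, match="matching"):
        PenaltyMatrices((1.0,), bad)
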