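"""Count-based binding rules: mismatch reports, the 3'-end rule, aggregation."""

import pytest
from hypothesis import given, strategies as st

from primerval import iupac
from primerval.binding import (
    BOUND,
    MISSING,
    UNBOUND,
    BindingParameters,
    BindingResult,
    SCORE_AS_MISMATCH,
    evaluate_pair,
    locate_primer,
    mismatch_report,
    test_binding as binding_status,
)
from primerval.exceptions import PrimervalError
from primerval.model import AlignedRecord, AlignedSequenceSet, DegeneratePrimer, PrimerPair
from primerval.similarity import build_consensus

FWD = DegeneratePrimer("f", "CCDGATATAG", "forward")
PARAMS = BindingParameters()


def test_perfect_match_report():
    rep = mismatch_report(FWD, "CCAGATATAG", PARAMS)
    assert rep.total == 0 and rep.three_prime_count == 0 and not rep.missing


def test_three_prime_terminal_bookkeeping():
    # mismatch at the primer's 3'-terminal base (last character for forward)
    rep = mismatch_report(FWD, "CCAGATATAC", PARAMS)
    assert rep.total == 1 and rep.three_prime_count == 1
    assert rep.per_position[-1] is True
    # same mismatch at the 5' end stays outside the terminal window
    rep5 = mismatch_report(FWD, "ACAGATATAG", PARAMS)
    assert rep5.total == 1 and rep5.three_prime_count == 0


def test_degenerate_position_accepts_covered_base():
    # template T under primer D = {A,G,T}: not a mismatch
    rep = mismatch_report(FWD, "CCTGATATAG", PARAMS)
    assert rep.total == 0


def test_reverse_primer_compared_on_its_own_orientation():
    rev = DegeneratePrimer("r", "ACGTTTTTTA", "reverse")
    plus_site = iupac.reverse_complement("ACGTTTTTTA")
    assert mismatch_report(rev, plus_site, PARAMS).total == 0
    # a mismatch at the plus-strand 5' end is the reverse primer's 3' terminus
    mutated = "G" + plus_site[1:]
    rep = mismatch_report(rev, mutated, PARAMS)
    assert rep.total == 1 and rep.three_prime_count == 1


def test_missing_policy():
    gapped = "CC-GATATAG"
    rep = mismatch_report(FWD, gapped, PARAMS)
    assert rep.missing
    assert binding_status(rep, PARAMS) == MISSING
    lenient = BindingParameters(missing_policy=SCORE_AS_MISMATCH)
    rep2 = mismatch_report(FWD, gapped, lenient)
    assert not rep2.missing and rep2.total == 1
    assert binding_status(rep2, lenient) == BOUND


@pytest.mark.parametrize(
    "total, tp, expected",
    [(3, 0, BOUND), (4, 0, UNBOUND), (1, 1, UNBOUND), (0, 0, BOUND)],
)
def test_binding_rule_boundaries(total, tp, expected):
    primer = DegeneratePrimer("p", "A" * 10, "forward")
    site = list("A" * 10)
    # place tp mismatches in the terminal window, the rest 5'-first
    for k in range(tp):
        site[9 - k] = "C"
    for k in range(total - tp):
        site[k] = "C"
    rep = mismatch_report(primer, "".join(site), PARAMS)
    assert (rep.total, rep.three_prime_count) == (total, tp)
    assert binding_status(rep, PARAMS) == expected


def test_length_mismatch_rejected():
    with pytest.raises(PrimervalError, match="length"):
        mismatch_report(FWD, "ACGT", PARAMS)


primers_small = st.text(alphabet=sorted(iupac.CODE_SETS), min_size=4, max_size=8).filter(
    lambda s: iupac.degeneracy(s) <= 64
)
templates = st.text(alphabet="ACGT", min_size=8, max_size=8)


@given(primers_small, templates)
def test_bound_equals_enumeration_oracle(pseq, tseq):
    """Bound status equals the minimum-Hamming rule over all expansions."""
    tseq = tseq[: len(pseq)]
    primer = DegeneratePrimer("p", pseq, "forward")
    rep = mismatch_report(primer, tseq, PARAMS)
    window = min(PARAMS.three_prime_window, len(pseq))

    best = None
    for exp in primer.expansions():
        mism = [a != b for a, b in zip(exp, tseq)]
        key = (sum(mism), sum(mism[len(pseq) - window :]))
        ok = key[0] <= PARAMS.max_total_mismatch and key[1] <= PARAMS.max_three_prime_mismatch
        best = best or ok
    assert (binding_status(rep, PARAMS) == BOUND) == best


def test_parameter_monotonicity(scenario):
    truth, pairs, aln, _ = scenario
    loose = BindingParameters(max_total_mismatch=4, max_three_prime_mismatch=1)
    strict = BindingParameters(max_total_mismatch=2, max_three_prime_mismatch=0)
    res_loose = evaluate_pair(aln, pairs["AscCOI2"], loose)
    res_mid = evaluate_pair(aln, pairs["AscCOI2"], PARAMS)
    res_strict = evaluate_pair(aln, pairs["AscCOI2"], strict)
    for which in ("forward", "reverse", "pair"):
        assert (
            res_strict.bound_sequences(which)
            <= res_mid.bound_sequences(which)
            <= res_loose.bound_sequences(which)
        )


def test_evaluate_pair_engineered_counts():
    """10 sequences, 4 engineered with >= 4 reverse mismatches -> 6 pair-bound."""
    fwd = DegeneratePrimer("f", "ACGTACGTAC", "forward")
    rev = DegeneratePrimer("r", "GGGGGGGGGG", "reverse")
    fwd_site = "ACGTACGTAC"
    rev_plus = iupac.reverse_complement("GGGGGGGGGG")  # CCCC...
    recs = []
    for i in range(10):
        rev_site = rev_plus if i < 6 else "TTTT" + rev_plus[4:]
        recs.append(
            AlignedRecord(f"s{i}", f"sp{i // 2}", "", fwd_site + "AAAA" + rev_site)
        )
    aln = AlignedSequenceSet(recs)
    pair = PrimerPair(fwd, rev, forward_site=(1, 10), reverse_site=(15, 24))
    res = evaluate_pair(aln, pair, PARAMS)
    assert res.bound_sequences("pair") == 6
    assert res.bound_sequences("forward") == 10
    # species bound iff >= 1 pair-bound sequence (partition check)
    bound_species = {
        r.species
        for r, st_ in zip(aln, res.detail["pair_status"])
        if st_ == BOUND
    }
    assert res.bound_species("pair") == len(bound_species) == 3


def test_all_identical_alignment_fully_bound():
    fwd = DegeneratePrimer("f", "ACGWACGTAC", "forward")
    rev = DegeneratePrimer("r", "ACGTACGTAC", "reverse")
    expansion = sorted(fwd.expansions())[0]
    seq = expansion + "CCCC" + iupac.reverse_complement(rev.sequence)
    aln = AlignedSequenceSet([AlignedRecord(f"s{i}", "sp", "", seq) for i in range(5)])
    pair = PrimerPair(fwd, rev, forward_site=(1, 10), reverse_site=(15, 24))
    res = evaluate_pair(aln, pair)
    assert res.bound_sequences("pair") == 5
    assert res.bound_species("pair") == 1


def test_locate_primer_prefers_five_prime_most_tie():
    cols = "AAAAGGGGAAAA"
    aln = AlignedSequenceSet([AlignedRecord("s", "sp", "", cols)] * 2)
    cons = build_consensus(aln)
    primer = DegeneratePrimer("p", "AAAA", "forward")
    assert locate_primer(primer, cons) == (1, 4)  # ties at (9,12) resolved 5'-most
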