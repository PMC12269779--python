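"""K80 pairwise distances and the barcoding gap."""

import numpy as np
import pandas as pd
import pytest

from primerval.distances import (
    BarcodingGapResult,
    distance_matrix,
    gap_statistics,
    k80_distance,
)
from primerval.exceptions import PrimervalError
from primerval.model import AlignedRecord, AlignedSequenceSet
from primerval.simulate import k80_evolve

_BASES = np.array(list("ACGT"))


def test_identical_sequences():
    p, q, d, valid = k80_distance("ACGTACGT", "ACGTACGT")
    assert (p, q, d, valid) == (0.0, 0.0, 0.0, True)


def test_closed_form_example():
    """100 sites, 10 transitions, 5 transversions -> d = -0.5 ln(0.75 sqrt(0.9))."""
    a = list("A" * 100)
    b = list("A" * 100)
    for i in range(10):
        b[i] = "G"  # transition
    for i in range(10, 15):
        b[i] = "C"  # transversion
    p, q, d, valid = k80_distance("".join(a), "".join(b))
    assert (p, q) == (0.10, 0.05)
    assert valid
    assert d == pytest.approx(0.17018, abs=5e-6)
    assert d == pytest.approx(-0.5 * np.log(0.75 * np.sqrt(0.90)), abs=1e-12)


def test_saturation_is_invalid():
    a = "A" * 100
    b = "G" * 50 + "A" * 50  # P = 0.5, Q = 0
    p, q, d, valid = k80_distance(a, b)
    assert (p, q) == (0.5, 0.0)
    assert not valid and np.isnan(d)


def test_pairwise_deletion_and_min_overlap():
    a = "ACGT-NACGT"
    b = "ACGTAA-CGT"
    # compared sites: 1-4 and 8-10 only (gap or N on either side is skipped)
    p, q, d, valid = k80_distance(a, b)
    assert valid and (p, q, d) == (0.0, 0.0, 0.0)
    _, _, _, valid_strict = k80_distance(a, b, min_overlap=50)
    assert not valid_strict


def test_symmetry():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = "".join(rng.choice(list("ACGT-N"), size=200))
        b = "".join(rng.choice(list("ACGT-N"), size=200))
        fwd, rev = k80_distance(a, b, 10), k80_distance(b, a, 10)
        assert fwd == rev or (
            fwd[:2] == rev[:2] and np.isnan(fwd[2]) and np.isnan(rev[2]) and fwd[3] == rev[3]
        )


def test_length_mismatch_rejected():
    with pytest.raises(PrimervalError):
        k80_distance("ACGT", "ACG")


def test_distance_exceeds_observed_divergence():
    """Multiple-hit correction: d >= P + Q, tight for small divergence."""
    rng = np.random.default_rng(1)
    base = rng.integers(0, 4, size=2000)
    for target in (0.01, 0.03, 0.05):
        other = k80_evolve(base, target, 2.0, rng)
        p, q, d, valid = k80_distance("".join(_BASES[base]), "".join(_BASES[other]))
        assert valid
        assert d >= p + q - 1e-12
        if p + q <= 0.05:
            assert d == pytest.approx(p + q, rel=0.10)


def test_estimator_consistency_on_simulated_k80():
    """Mean estimated distance within 3 SE of the simulated branch length."""
    rng = np.random.default_rng(2)
    n_sites, true_d, reps = 10_000, 0.15, 30
    estimates = []
    for _ in range(reps):
        anc = rng.integers(0, 4, size=n_sites)
        der = k80_evolve(anc, true_d, 2.0, rng)
        _, _, d, valid = k80_distance("".join(_BASES[anc]), "".join(_BASES[der]))
        assert valid
        estimates.append(d)
    mean = np.mean(estimates)
    se = np.std(estimates, ddof=1) / np.sqrt(reps)
    assert abs(mean - true_d) < 3 * se


def aln_of(seqs, species):
    return AlignedSequenceSet(
        [AlignedRecord(f"s{i}", sp, "", s) for i, (s, sp) in enumerate(zip(seqs, species))]
    )


def test_pair_combinatorics():
    seqs = ["ACGTACGTAC"] * 4
    dists = distance_matrix(aln_of(seqs, ["a", "a", "b", "b"]), min_overlap=1)
    assert len(dists) == 6
    assert (dists["comparison"] == "intra").sum() == 2
    assert (dists["comparison"] == "inter").sum() == 4


def test_two_level_divergence_orders_means(scenario):
    truth, _, aln, _ = scenario
    dists = distance_matrix(aln)
    valid = dists[dists["valid"]]
    intra = valid.loc[valid["comparison"] == "intra", "distance"]
    inter = valid.loc[valid["comparison"] == "inter", "distance"]
    assert intra.mean() < inter.mean()
    gap = gap_statistics(dists)
    assert gap.gap > 0
    assert gap.n_intra + gap.n_inter + gap.n_invalid == len(dists)


def frame(intra, inter):
    rows = [("a", "b", "intra", 0.0, 0.0, d, True) for d in intra]
    rows += [("a", "c", "inter", 0.0, 0.0, d, True) for d in inter]
    return pd.DataFrame(rows, columns=["id_a", "id_b", "comparison", "P", "Q", "distance", "valid"])


def test_gap_arithmetic_and_histograms():
    res = gap_statistics(frame([0.01, 0.02], [0.10, 0.30]), bin_width=0.01)
    assert res.max_intra == 0.02 and res.min_inter == 0.10
    assert res.gap == pytest.approx(0.08)
    assert res.intra_histogram.sum() == 2 and res.inter_histogram.sum() == 2


def test_negative_gap_not_clamped():
    res = gap_statistics(frame([0.05, 0.30], [0.10, 0.40]))
    assert res.gap == pytest.approx(0.10 - 0.30)


def test_missing_class_named_in_error():
    with pytest.raises(PrimervalError, match="interspecific"):
        gap_statistics(frame([0.01], []))
    with pytest.raises(PrimervalError, match="intraspecific"):
        gap_statistics(frame([], [0.1]))
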