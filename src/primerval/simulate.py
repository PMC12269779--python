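"""Seeded synthetic aligned COI-like datasets with known ground truth.

The generator emulates the structure of a curated barcode alignment:
per-species sequence groups with two-level divergence (small within
species, large between) under a Kimura two-parameter substitution
process, sprinkled gaps and ambiguity codes, and primer binding sites
overwritten to carry *exactly* a designed number of mismatches (total
and 3'-terminal) against specified primers.  Because the designed
counts are enforced and asserted, every downstream stage — binding
fractions, penalty classes, mixed-model effects, distance gaps — has a
known truth to recover.

All randomness is a pure function of the seed: the same
:class:`SyntheticTruth` yields byte-identical FASTA output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import iupac, published
from .binding import BindingParameters, mismatch_report
from .exceptions import PrimervalError
from .model import (
    FORWARD,
    AlignedRecord,
    AlignedSequenceSet,
    DegeneratePrimer,
    PrimerPair,
)

_BASES = np.array(list("ACGT"))
#: two-fold ambiguity codes used when injecting ambiguous residues
_TWOFOLD = ["R", "Y", "S", "W", "K", "M"]


@dataclass(frozen=True)
class SiteDesign:
    """A primer binding site with per-record designed mismatch counts.

    ``start`` is the 1-based plus-strand column of the site's first
    base.  ``mismatches[i]`` is (total, three_prime) for record i;
    ``missing[i]`` marks records whose site is written as all gaps
    (truncated, hence unevaluable downstream).  Mismatches are placed
    5'-first among positions where the primer code is not fully
    degenerate, except for the 3'-terminal count, which occupies the
    terminal-most eligible positions.
    """

    primer: DegeneratePrimer
    start: int
    mismatches: tuple[tuple[int, int], ...]
    missing: tuple[bool, ...] | None = None
    three_prime_window: int = 2

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.start + self.primer.length - 1)


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters; every field is part of the ground truth."""

    seed: int
    n_species: int = 40
    seqs_per_species: int | tuple[int, ...] = 6
    alignment_length: int = 700
    primer_sites: tuple[SiteDesign, ...] = ()
    ambiguity_rate: float = 0.002
    gap_rate: float = 0.01
    intra_rate: float = 0.02
    inter_rate: float = 0.35
    ts_tv_ratio: float = 2.0
    true_effect: float = 2.0
    species_sd: float = 1.0
    baseline_logit: float = -0.5
    taxon: str = "target"

    def group_sizes(self) -> list[int]:
        if isinstance(self.seqs_per_species, int):
            return [self.seqs_per_species] * self.n_species
        if len(self.seqs_per_species) != self.n_species:
            raise PrimervalError("per-species size list length != n_species")
        return list(self.seqs_per_species)

    @property
    def n_records(self) -> int:
        return sum(self.group_sizes())


def k80_evolve(codes: np.ndarray, distance: float, ts_tv_ratio: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve integer-coded bases (A0 C1 G2 T3) for an expected
    ``distance`` substitutions/site under K80.

    ``ts_tv_ratio`` is the expected transition:transversion event ratio
    R = alpha/(2 beta), so the realised substitution spectrum converges
    to it at low divergence."""
    if distance <= 0:
        return codes.copy()
    beta_t = distance / (2.0 * ts_tv_ratio + 2.0)
    alpha_t = 2.0 * ts_tv_ratio * beta_t
    e4b = np.exp(-4.0 * beta_t)
    e2ab = np.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv_each = 0.25 - 0.25 * e4b

    u = rng.random(codes.size)
    out = codes.copy()
    # transition partner: A<->G, C<->T  (XOR with 2 on the 0..3 coding)
    ts_mask = u < p_ts
    out[ts_mask] = codes[ts_mask] ^ 2
    tv1 = (u >= p_ts) & (u < p_ts + p_tv_each)
    tv2 = (u >= p_ts + p_tv_each) & (u < p_ts + 2 * p_tv_each)
    # transversion targets have opposite parity: {C,T} for purines, {A,G} for pyrimidines
    odd = (codes & 1).astype(bool)
    out[tv1] = np.where(odd[tv1], 0, 1)
    out[tv2] = np.where(odd[tv2], 2, 3)
    return out


def _designed_site(design: SiteDesign, i: int, rng: np.random.Generator) -> str:
    """Plus-strand template text for record i at a designed site."""
    primer = design.primer
    n = primer.length
    if design.missing is not None and design.missing[i]:
        return iupac.GAP * n

    total, tp = design.mismatches[i]
    if tp > total:
        raise PrimervalError("3'-terminal mismatch count exceeds total")
    if total > n:
        raise PrimervalError("designed mismatches exceed site length")

    # template in primer orientation: draw each base from the primer's set
    sets = [sorted(iupac.CODE_SETS[c]) for c in primer.sequence]
    tmpl = [s[rng.integers(len(s))] for s in sets]

    eligible = [k for k in range(n) if len(sets[k]) < 4]
    window = min(design.three_prime_window, n)
    term_eligible = [k for k in eligible if k >= n - window]
    body_eligible = [k for k in eligible if k < n - window]
    if tp > len(term_eligible) or (total - tp) > len(body_eligible):
        raise PrimervalError(
            f"cannot place {total} mismatches ({tp} terminal) on primer {primer.name!r}"
        )
    positions = sorted(term_eligible, reverse=True)[:tp] + body_eligible[: total - tp]
    for k in positions:
        tmpl[k] = sorted(set(iupac.CONCRETE) - set(sets[k]))[0]

    site = "".join(tmpl)
    if primer.orientation != FORWARD:
        site = iupac.reverse_complement(site)
    return site


def generate_alignment(truth: SyntheticTruth) -> tuple[AlignedSequenceSet, dict]:
    """Generate the alignment and its machine-readable truth record."""
    rng = np.random.default_rng(truth.seed)
    sizes = truth.group_sizes()
    length = truth.alignment_length

    constrained = np.zeros(length, dtype=bool)
    for design in truth.primer_sites:
        lo, hi = design.interval
        if lo < 1 or hi > length:
            raise PrimervalError(f"site {design.interval} outside alignment")
        if len(design.mismatches) != truth.n_records:
            raise PrimervalError("mismatch design length != number of records")
        constrained[lo - 1 : hi] = True

    root = rng.integers(0, 4, size=length)
    records: list[AlignedRecord] = []
    idx = 0
    for s, size in enumerate(sizes):
        ancestor = k80_evolve(root, truth.inter_rate / 2.0, truth.ts_tv_ratio, rng)
        for _ in range(size):
            codes = k80_evolve(ancestor, truth.intra_rate / 2.0, truth.ts_tv_ratio, rng)
            chars = _BASES[codes].copy()
            free = ~constrained
            gap_mask = free & (rng.random(length) < truth.gap_rate)
            chars[gap_mask] = iupac.GAP
            amb_mask = free & ~gap_mask & (rng.random(length) < truth.ambiguity_rate)
            for j in np.flatnonzero(amb_mask):
                if rng.random() < 0.5:
                    chars[j] = "N"
                else:  # a two-fold code covering the true base
                    options = [c for c in _TWOFOLD if chars[j] in iupac.CODE_SETS[c]]
                    chars[j] = options[rng.integers(len(options))]
            seq = list("".join(chars))
            for design in truth.primer_sites:
                lo, hi = design.interval
                seq[lo - 1 : hi] = _designed_site(design, idx, rng)
            records.append(
                AlignedRecord(
                    f"seq{idx + 1:04d}", f"species_{s + 1:03d}", truth.taxon, "".join(seq)
                )
            )
            idx += 1

    aln = AlignedSequenceSet(records)
    _assert_designs(aln, truth)
    truth_record = {
        "seed": truth.seed,
        "n_species": truth.n_species,
        "group_sizes": sizes,
        "alignment_length": length,
        "intra_rate": truth.intra_rate,
        "inter_rate": truth.inter_rate,
        "ts_tv_ratio": truth.ts_tv_ratio,
        "gap_rate": truth.gap_rate,
        "ambiguity_rate": truth.ambiguity_rate,
        "sites": [
            {
                "primer": d.primer.name,
                "interval": list(d.interval),
                "designed_mismatches": [list(m) for m in d.mismatches],
                "missing": list(d.missing) if d.missing is not None else None,
            }
            for d in truth.primer_sites
        ],
    }
    return aln, truth_record


def _assert_designs(aln: AlignedSequenceSet, truth: SyntheticTruth) -> None:
    """Realized mismatch counts at constrained sites must equal the design."""
    params = BindingParameters()
    for design in truth.primer_sites:
        for i, rec in enumerate(aln):
            site = aln.site(rec, design.interval)
            if design.missing is not None and design.missing[i]:
                assert set(site) == {iupac.GAP}, "designed-missing site not all gaps"
                continue
            rep = mismatch_report(design.primer, site, params)
            total, tp = design.mismatches[i]
            assert rep.total == total and rep.three_prime_count == tp, (
                f"realized mismatches ({rep.total},{rep.three_prime_count}) != "
                f"designed ({total},{tp}) for {design.primer.name} record {i}"
            )


def design_schedule(
    n_records: int,
    fractions: dict[tuple[int, int], float],
    rng: np.random.Generator,
    missing_fraction: float = 0.0,
) -> tuple[tuple[tuple[int, int], ...], tuple[bool, ...]]:
    """Assign designed (total, 3') mismatch counts to records.

    ``fractions`` maps a (total, three_prime) design to the fraction of
    records that should carry it; counts are rounded to integers and the
    remainder of records get a perfect (0, 0) site.  Assignment order is
    a seeded permutation so designs are spread across species.
    """
    n_missing = int(round(missing_fraction * n_records))
    pool: list[tuple[tuple[int, int], bool]] = []
    for mm, frac in fractions.items():
        pool.extend([(mm, False)] * int(round(frac * n_records)))
    if len(pool) + n_missing > n_records:
        raise PrimervalError("design fractions exceed 1")
    pool.extend([((0, 0), True)] * n_missing)
    pool.extend([((0, 0), False)] * (n_records - len(pool)))
    order = rng.permutation(n_records)
    mm_out: list[tuple[int, int]] = [(0, 0)] * n_records
    miss_out = [False] * n_records
    for slot, rec in enumerate(order):
        mm_out[rec], miss_out[rec] = pool[slot]
    return tuple(mm_out), tuple(miss_out)


def generate_binding_outcomes(truth: SyntheticTruth) -> tuple[pd.DataFrame, dict]:
    """Bernoulli amplification records drawn from the logistic model the
    mixed model assumes: logit P = baseline + effect*[improved] + u_species."""
    if truth.n_species < 2:
        raise PrimervalError("need >= 2 species for a species random intercept")
    rng = np.random.default_rng(truth.seed)
    sizes = truth.group_sizes()
    intercepts = rng.normal(0.0, truth.species_sd, size=truth.n_species)
    rows = []
    idx = 0
    for s, size in enumerate(sizes):
        for _ in range(size):
            idx += 1
            for label, shift in (("reference", 0.0), ("improved", truth.true_effect)):
                logit = truth.baseline_logit + shift + intercepts[s]
                p = 1.0 / (1.0 + np.exp(-logit))
                rows.append(
                    {
                        "sequence_id": f"seq{idx:04d}",
                        "species": f"species_{s + 1:03d}",
                        "primer_set": label,
                        "outcome": int(rng.random() < p),
                    }
                )
    params = {
        "true_effect": truth.true_effect,
        "species_sd": truth.species_sd,
        "baseline_logit": truth.baseline_logit,
        "n_species": truth.n_species,
        "n_records": truth.n_records,
    }
    return pd.DataFrame(rows), params


def default_scenario(seed: int) -> tuple[SyntheticTruth, dict[str, PrimerPair]]:
    """Desk-scale study conditions mirroring the real dataset's shape.

    Two primer pairs are placed at disjoint designed sites on one
    target-group alignment.  The reference pair's reverse site carries
    designed failures in ~25% of records (plus a few 3'-terminal-rule
    failures and a small missing fraction); the improved pair's reverse
    site fails in ~15%, reproducing the qualitative published contrast
    (reverse-primer binding drives the pair-level difference).
    """
    base = SyntheticTruth(seed=seed)
    n = base.n_records
    rng = np.random.default_rng(seed + 1)

    f1 = published.ASCCOI_F
    r1 = published.ASCCOI_R
    f2 = published.ASCCOI2_F
    r2 = published.ASCCOI2_R

    mm_f1, miss_f1 = design_schedule(n, {(4, 0): 0.10, (1, 0): 0.20}, rng, missing_fraction=0.004)
    mm_r1, miss_r1 = design_schedule(n, {(4, 0): 0.20, (1, 1): 0.05, (2, 0): 0.20}, rng)
    mm_f2, miss_f2 = design_schedule(n, {(1, 0): 0.25}, rng)
    mm_r2, miss_r2 = design_schedule(n, {(4, 0): 0.10, (1, 1): 0.05, (2, 0): 0.25}, rng)

    sites = (
        SiteDesign(f1, 101, mm_f1, miss_f1),
        SiteDesign(f2, 151, mm_f2, miss_f2),
        SiteDesign(r1, 301, mm_r1, miss_r1),
        SiteDesign(r2, 361, mm_r2, miss_r2),
    )
    truth = replace(base, primer_sites=sites)
    pairs = {
        "AscCOI": PrimerPair(f1, r1, forward_site=(101, 120), reverse_site=(301, 323)),
        "AscCOI2": PrimerPair(f2, r2, forward_site=(151, 170), reverse_site=(361, 383)),
    }
    return truth, pairs


def write_outputs(
    aln: AlignedSequenceSet, truth_record: dict, outdir: str | Path
) -> dict[str, Path]:
    """Write FASTA + species map TSV + truth JSON; returns the paths."""
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "synthetic_alignment.fasta",
        "species_map": outdir / "species_map.tsv",
        "truth": outdir / "truth.json",
    }
    pio.write_aligned_fasta(aln, paths["fasta"])
    pio.write_species_map(aln, paths["species_map"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth_record, fh, indent=2)
    return paths
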