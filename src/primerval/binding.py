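"""Mismatch-rule binding test of primer pairs against aligned sequences.

A primer is considered to bind a template when the number of
mismatching positions (subset-rule IUPAC matching) does not exceed a
total cap anywhere in the binding region and a stricter cap inside a
short window at the 3' terminus — the extension end, where mismatches
are most disruptive to the polymerase.  Defaults: at most 3 mismatches
in total, none in the terminal 2 bases.

Results are aggregated at the sequence level and at the species level,
where a species counts as covered when at least one of its sequences is
bound by both primers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import iupac
from .exceptions import AlignmentError, PrimervalError
from .model import FORWARD, AlignedSequenceSet, DegeneratePrimer, PrimerPair
from .similarity import ConsensusSequence, build_consensus

BOUND = "bound"
UNBOUND = "unbound"
MISSING = "missing"

MISSING_IF_GAP = "missing_if_gap_or_incomplete"
SCORE_AS_MISMATCH = "score_as_mismatch"


@dataclass(frozen=True)
class BindingParameters:
    """Count-based binding rule.

    ``missing_policy`` controls gap-containing sites: under
    ``missing_if_gap_or_incomplete`` such a site is neither bound nor
    unbound (excluded from the bound numerator, kept in denominators);
    under ``score_as_mismatch`` each gapped position simply counts as a
    mismatch.
    """

    max_total_mismatch: int = 3
    three_prime_window: int = 2
    max_three_prime_mismatch: int = 0
    missing_policy: str = MISSING_IF_GAP

    def __post_init__(self) -> None:
        if min(self.max_total_mismatch, self.three_prime_window, self.max_three_prime_mismatch) < 0:
            raise ValueError("binding parameters must be non-negative")
        if self.missing_policy not in (MISSING_IF_GAP, SCORE_AS_MISMATCH):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass(frozen=True)
class MismatchReport:
    """Per-position mismatch flags, indexed from the primer's 5' end."""

    per_position: tuple[bool, ...]
    total: int
    three_prime_count: int
    missing: bool


def mismatch_report(
    primer: DegeneratePrimer,
    template_site: str,
    params: BindingParameters = BindingParameters(),
) -> MismatchReport:
    """Compare a primer with its plus-strand template site.

    ``template_site`` is always given on the plus strand; reverse
    primers are compared after reverse-complementing the site so that
    position bookkeeping (and the 3' window) follows the primer's own
    5'->3' orientation.
    """
    site = iupac.normalize(template_site, allow_gap=True, context="template site")
    if len(site) != primer.length:
        raise PrimervalError(
            f"template site length {len(site)} != primer {primer.name!r} "
            f"length {primer.length}"
        )
    if primer.orientation != FORWARD:
        site = _reverse_complement_gapped(site)

    flags = tuple(
        not iupac.base_matches(p, t) for p, t in zip(primer.sequence, site)
    )
    window = min(params.three_prime_window, primer.length)
    has_gap = iupac.GAP in site
    missing = has_gap and params.missing_policy == MISSING_IF_GAP
    return MismatchReport(
        per_position=flags,
        total=sum(flags),
        three_prime_count=sum(flags[primer.length - window :]),
        missing=missing,
    )


def _reverse_complement_gapped(site: str) -> str:
    parts = [
        iupac.GAP if c == iupac.GAP else iupac.reverse_complement(c) for c in reversed(site)
    ]
    return "".join(parts)


def test_binding(report: MismatchReport, params: BindingParameters = BindingParameters()) -> str:
    """Classify a mismatch report as bound / unbound / missing."""
    if report.missing:
        return MISSING
    if (
        report.total <= params.max_total_mismatch
        and report.three_prime_count <= params.max_three_prime_mismatch
    ):
        return BOUND
    return UNBOUND


def locate_primer(
    primer: DegeneratePrimer,
    consensus: ConsensusSequence,
) -> tuple[int, int]:
    """Deterministic placement: the window minimising total mismatches
    against the consensus, ties broken toward the 5'-most (leftmost)
    start column.  Returns a 1-based inclusive interval."""
    site_len = primer.length
    length = len(consensus)
    if site_len > length:
        raise AlignmentError("primer longer than alignment")
    plus = primer.site_on_plus_strand()
    best_start, best_mm = 0, site_len + 1
    for start in range(length - site_len + 1):
        window = consensus.codes[start : start + site_len]
        mm = sum(not iupac.base_matches(p, t) for p, t in zip(plus, window))
        if mm < best_mm:
            best_start, best_mm = start, mm
    return (best_start + 1, best_start + site_len)


@dataclass
class BindingResult:
    """Per-sequence binding outcomes plus summary-table aggregation."""

    pair: PrimerPair
    params: BindingParameters
    detail: pd.DataFrame  # sequence_id, species, taxon, fwd_*, rev_*, status columns
    forward_site: tuple[int, int]
    reverse_site: tuple[int, int]

    @property
    def n_sequences(self) -> int:
        return len(self.detail)

    @property
    def n_species(self) -> int:
        return self.detail["species"].nunique()

    def bound_sequences(self, which: str = "pair") -> int:
        return int((self.detail[f"{which}_status"] == BOUND).sum())

    def bound_species(self, which: str = "pair") -> int:
        mask = self.detail[f"{which}_status"] == BOUND
        return self.detail.loc[mask, "species"].nunique()

    def summary_table(self) -> pd.DataFrame:
        """Two-row summary (species level, sequence level) per primer and pair."""
        rows = []
        for level, total in (("species", self.n_species), ("sequence", self.n_sequences)):
            row: dict[str, object] = {"level": level, "total": total}
            for which in ("forward", "reverse", "pair"):
                n = self.bound_species(which) if level == "species" else self.bound_sequences(which)
                row[which] = n
                row[f"{which}_pct"] = round(100.0 * n / total, 2) if total else float("nan")
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate_pair(
    aln: AlignedSequenceSet,
    pair: PrimerPair,
    params: BindingParameters = BindingParameters(),
    consensus: ConsensusSequence | None = None,
) -> BindingResult:
    """Test every record of the alignment against both primers.

    A sequence is bound by the pair iff bound by both primers; a
    species is covered iff at least one of its sequences is pair-bound.
    Sites come from the pair's stored intervals or, when unset, from
    :func:`locate_primer` against the alignment consensus.
    """
    if len(aln) == 0:
        raise PrimervalError("empty alignment")
    fwd_site = pair.forward_site
    rev_site = pair.reverse_site
    if fwd_site is None or rev_site is None:
        if consensus is None:
            consensus = build_consensus(aln)
        if fwd_site is None:
            fwd_site = locate_primer(pair.forward, consensus)
        if rev_site is None:
            rev_site = locate_primer(pair.reverse, consensus)
    for site in (fwd_site, rev_site):
        if site[0] < 1 or site[1] > aln.alignment_length:
            raise AlignmentError(f"site {site} outside alignment")

    rows = []
    for rec in aln:
        frep = mismatch_report(pair.forward, aln.site(rec, fwd_site), params)
        rrep = mismatch_report(pair.reverse, aln.site(rec, rev_site), params)
        fstat = test_binding(frep, params)
        rstat = test_binding(rrep, params)
        if MISSING in (fstat, rstat):
            pstat = MISSING
        elif fstat == BOUND and rstat == BOUND:
            pstat = BOUND
        else:
            pstat = UNBOUND
        rows.append(
            {
                "sequence_id": rec.sequence_id,
                "species": rec.species,
                "taxon": rec.taxon,
                "fwd_total": frep.total,
                "fwd_3p": frep.three_prime_count,
                "forward_status": fstat,
                "rev_total": rrep.total,
                "rev_3p": rrep.three_prime_count,
                "reverse_status": rstat,
                "pair_status": pstat,
            }
        )
    detail = pd.DataFrame(rows)
    return BindingResult(pair, params, detail, fwd_site, rev_site)
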