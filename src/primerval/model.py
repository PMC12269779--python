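"""Core domain types: degenerate primers, primer pairs, aligned sequence sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator

import numpy as np

from . import iupac
from .exceptions import AlignmentError, AlphabetError

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class DegeneratePrimer:
    """A 5'->3' IUPAC primer with an orientation.

    ``sequence`` is stored normalised (upper case, U->T) and validated
    against the 15-letter IUPAC alphabet; gaps are not allowed.
    """

    name: str
    sequence: str
    orientation: str = FORWARD

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(
                f"orientation must be {FORWARD!r} or {REVERSE!r}, got {self.orientation!r}"
            )
        seq = iupac.normalize(self.sequence, context=f"primer {self.name!r}")
        if len(seq) < 1:
            raise ValueError(f"primer {self.name!r} is empty")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return iupac.degeneracy(self.sequence)

    def expansions(self) -> set[str]:
        """All concrete sequences this primer represents."""
        return iupac.expand(self.sequence)

    def site_on_plus_strand(self) -> str:
        """The primer as it reads on the alignment's plus strand.

        Forward primers anneal to the minus strand and read as-is on
        the plus strand; reverse primers are reverse-complemented.
        """
        if self.orientation == FORWARD:
            return self.sequence
        return iupac.reverse_complement(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with optional alignment placement.

    Sites are 1-based inclusive column intervals on the plus strand.
    ``expected_amplicon`` is descriptive metadata stored as supplied
    (published amplicon sizes need not equal the alignment span, e.g.
    when the alignment contains indel columns); use :meth:`site_span`
    for the span implied by the placements.
    """

    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    forward_site: tuple[int, int] | None = None
    reverse_site: tuple[int, int] | None = None
    expected_amplicon: int | None = None

    def __post_init__(self) -> None:
        if self.forward.orientation != FORWARD:
            raise ValueError("forward member must have forward orientation")
        if self.reverse.orientation != REVERSE:
            raise ValueError("reverse member must have reverse orientation")
        for site, primer in ((self.forward_site, self.forward), (self.reverse_site, self.reverse)):
            if site is not None:
                lo, hi = site
                if lo < 1 or hi < lo:
                    raise ValueError(f"invalid site interval {site}")
                if hi - lo + 1 != primer.length:
                    raise ValueError(
                        f"site {site} does not span primer {primer.name!r} "
                        f"(length {primer.length})"
                    )
        if self.forward_site is not None and self.reverse_site is not None:
            if self.forward_site[1] >= self.reverse_site[0]:
                raise ValueError("forward site must precede reverse site without overlap")

    @property
    def name(self) -> str:
        common = _common_prefix(self.forward.name, self.reverse.name).rstrip("_-")
        return common or f"{self.forward.name}/{self.reverse.name}"

    def site_span(self) -> int | None:
        """Plus-strand span from forward start to reverse end, in columns."""
        if self.forward_site is None or self.reverse_site is None:
            return None
        return self.reverse_site[1] - self.forward_site[0] + 1


def _common_prefix(a: str, b: str) -> str:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return a[:n]


@dataclass(frozen=True)
class AlignedRecord:
    sequence_id: str
    species: str
    taxon: str
    sequence: str


@dataclass
class AlignedSequenceSet:
    """Equal-length gapped sequences with species / taxon labels."""

    records: list[AlignedRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            return
        length = len(self.records[0].sequence)
        for i, rec in enumerate(self.records, start=1):
            if len(rec.sequence) != length:
                raise AlignmentError(
                    f"record {i} ({rec.sequence_id!r}) has length "
                    f"{len(rec.sequence)}, expected {length}"
                )
            if not rec.species:
                raise AlignmentError(f"record {i} ({rec.sequence_id!r}) has no species label")
            for j, ch in enumerate(rec.sequence):
                if ch not in iupac.CODE_SETS and ch != iupac.GAP:
                    raise AlphabetError(
                        f"invalid character {ch!r} at column {j + 1} of record "
                        f"{rec.sequence_id!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AlignedRecord]:
        return iter(self.records)

    @property
    def alignment_length(self) -> int:
        if not self.records:
            return 0
        return len(self.records[0].sequence)

    @property
    def species_labels(self) -> list[str]:
        return [r.species for r in self.records]

    def species_partition(self) -> dict[str, list[AlignedRecord]]:
        part: dict[str, list[AlignedRecord]] = {}
        for rec in self.records:
            part.setdefault(rec.species, []).append(rec)
        return part

    @property
    def n_species(self) -> int:
        return len({r.species for r in self.records})

    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.taxon or "", None)
        return list(seen)

    def subset_taxon(self, taxon: str) -> "AlignedSequenceSet":
        return AlignedSequenceSet([r for r in self.records if r.taxon == taxon])

    def site(self, record: AlignedRecord, interval: tuple[int, int]) -> str:
        """Extract a 1-based inclusive column interval from one record."""
        lo, hi = interval
        if lo < 1 or hi > self.alignment_length:
            raise AlignmentError(
                f"interval {interval} outside alignment of length {self.alignment_length}"
            )
        return record.sequence[lo - 1 : hi]

    @cached_property
    def char_matrix(self) -> np.ndarray:
        """(n_records, alignment_length) array of single characters."""
        return np.array([list(r.sequence) for r in self.records], dtype="U1")


def concatenate(a: AlignedSequenceSet, b: AlignedSequenceSet) -> AlignedSequenceSet:
    """Column-wise concatenation of two alignments over the same records."""
    if len(a) != len(b):
        raise AlignmentError("alignments have different record counts")
    recs = [
        AlignedRecord(ra.sequence_id, ra.species, ra.taxon, ra.sequence + rb.sequence)
        for ra, rb in zip(a, b)
    ]
    return AlignedSequenceSet(recs)
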