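"""IUPAC nucleotide algebra for degenerate oligonucleotides.

A degenerate primer position is a *set* of concrete bases denoted by a
single IUPAC ambiguity code (``R`` = {A,G}, ``N`` = {A,C,G,T}, ...).
All primer/template comparison logic in this package reduces to set
operations on these codes; this module owns the code table (taken from
Biopython's IUPAC data), expansion, complementation and the boolean
match test used by the binding analysis.

Matching uses *subset semantics*: a template code matches a primer code
iff every base the template could be is covered by the primer set.  A
concrete template base therefore matches iff it is a member of the
primer set, while an ambiguous template code that only partially
overlaps the primer set counts as a mismatch (fractional credit for
partial overlap exists only in penalty scoring, not here).
"""

from __future__ import annotations

import itertools
import math

from Bio.Data import IUPACData
from Bio.Seq import Seq

from .exceptions import AlphabetError

GAP = "-"

#: IUPAC code -> frozenset of concrete bases (15 codes; X excluded as
#: a non-standard alias of N).
CODE_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in IUPACData.ambiguous_dna_values.items()
    if code != "X"
}

CONCRETE = ("A", "C", "G", "T")

#: frozenset of bases -> minimal IUPAC code covering exactly that set.
SET_CODES: dict[frozenset[str], str] = {v: k for k, v in CODE_SETS.items()}


def normalize(sequence: str, *, allow_gap: bool = False, context: str = "sequence") -> str:
    """Upper-case a nucleotide string, map U->T and validate the alphabet.

    Raises :class:`AlphabetError` naming the 1-based position of the
    first offending character.
    """
    out = sequence.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch in CODE_SETS:
            continue
        if ch == GAP and allow_gap:
            continue
        raise AlphabetError(
            f"invalid character {ch!r} at position {i + 1} in {context}"
        )
    return out


def degeneracy(sequence: str) -> int:
    """Degree of degeneration D: product of per-position IUPAC set sizes."""
    return math.prod(len(CODE_SETS[c]) for c in sequence)


def expand(sequence: str) -> set[str]:
    """All concrete A/C/G/T sequences a degenerate sequence represents."""
    pools = [sorted(CODE_SETS[c]) for c in sequence]
    return {"".join(p) for p in itertools.product(*pools)}


def reverse_complement(sequence: str) -> str:
    """Reverse complement preserving ambiguity codes (R<->Y, K<->M, ...)."""
    seq = normalize(sequence, context="reverse_complement input")
    return str(Seq(seq).reverse_complement())


def base_matches(primer_code: str, template_code: str) -> bool:
    """Subset-rule match test between one primer and one template code.

    True iff the template's base set is a subset of the primer's base
    set.  A gap in the template never matches; a gap in the primer is an
    error (primers contain no gaps).
    """
    if primer_code == GAP:
        raise AlphabetError("primer positions cannot be gaps")
    if template_code == GAP:
        return False
    try:
        p = CODE_SETS[primer_code]
        t = CODE_SETS[template_code]
    except KeyError as exc:
        raise AlphabetError(f"invalid IUPAC code {exc.args[0]!r}") from None
    return t <= p
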