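"""Exception hierarchy for primerval."""


class PrimervalError(Exception):
    """Base class for all primerval errors."""


class AlphabetError(PrimervalError, ValueError):
    """A sequence contains a character outside the IUPAC alphabet."""


class AlignmentError(PrimervalError, ValueError):
    """Alignment records are inconsistent (e.g. ragged lengths)."""


class LabelingError(PrimervalError, ValueError):
    """A record header cannot be mapped to a species label."""


class SeparationError(PrimervalError, ValueError):
    """Complete separation: a logistic fit has no finite maximum.

    Raised when one primer set has all-identical outcomes, so the
    log-odds difference diverges; an exact or penalised method would be
    needed instead.
    """
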