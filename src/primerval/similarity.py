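"""Consensus calling and sliding-window conservation profiling.

The conservation of a candidate primer-binding region is summarised by
the similarity index 1/D, where D (the degree of degeneration) is the
number of concrete sequence variants a window of the IUPAC consensus
represents — the product of per-column ambiguity-set sizes.  A window
of fully conserved columns has D = 1 and index 1.0; every ambiguous
column multiplies D by its set size and shrinks the index toward 0.
A second per-column track records the proportion of records with a
non-gap residue, i.e. how much of the dataset actually covers each
column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import iupac
from .exceptions import PrimervalError
from .model import AlignedSequenceSet

DEFAULT_INCLUSION_THRESHOLD = 0.05
DEFAULT_WINDOW = 20
DEFAULT_STEP = 1


@dataclass(frozen=True)
class ConsensusSequence:
    """Per-column IUPAC consensus plus the non-gap coverage track.

    Each code is the minimal IUPAC code covering every base whose
    frequency among non-gap residues in that column is at least
    ``inclusion_threshold``, and always covers the single most frequent
    base.  All-gap columns are called ``N`` with coverage 0.
    """

    codes: str
    inclusion_threshold: float
    nongap_proportion: np.ndarray  # shape (alignment_length,)

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def low_coverage_columns(self) -> np.ndarray:
        """1-based columns where fewer than half the records have a residue."""
        return np.flatnonzero(self.nongap_proportion < 0.5) + 1


@dataclass(frozen=True)
class SimilarityProfile:
    """Sliding-window 1/D conservation index over a consensus."""

    window_size: int
    step: int
    window_start: np.ndarray  # 1-based start columns
    degeneration: np.ndarray  # D per window (float; D can exceed 2**63)
    index: np.ndarray  # 1/D per window
    proportion: np.ndarray  # mean non-gap proportion per window

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": self.window_start,
                "D": self.degeneration,
                "similarity_index": self.index,
                "mean_proportion": self.proportion,
            }
        )


def build_consensus(
    aln: AlignedSequenceSet,
    inclusion_threshold: float = DEFAULT_INCLUSION_THRESHOLD,
) -> ConsensusSequence:
    """Call the IUPAC consensus of an alignment.

    Ambiguous residues in the input contribute fractionally to each
    base in their set (an ``R`` counts half toward A and half toward G)
    so that rare sequencing ambiguities do not inflate the consensus
    beyond the ``inclusion_threshold`` rule.
    """
    if len(aln) == 0:
        raise PrimervalError("cannot build a consensus of an empty alignment")
    if not 0 <= inclusion_threshold < 1:
        raise ValueError("inclusion_threshold must be in [0, 1)")

    chars = aln.char_matrix  # (n, L)
    n, length = chars.shape
    counts = np.zeros((4, length))  # rows A, C, G, T
    base_index = {b: i for i, b in enumerate(iupac.CONCRETE)}
    for code, bases in iupac.CODE_SETS.items():
        mask = chars == code
        if not mask.any():
            continue
        weight = 1.0 / len(bases)
        col_counts = mask.sum(axis=0)
        for b in bases:
            counts[base_index[b]] += weight * col_counts

    nongap = (chars != iupac.GAP).sum(axis=0)
    proportion = nongap / n

    codes = []
    for j in range(length):
        total = counts[:, j].sum()
        if total == 0:  # all-gap column
            codes.append("N")
            continue
        freqs = counts[:, j] / total
        keep = {
            iupac.CONCRETE[i]
            for i in range(4)
            if freqs[i] >= inclusion_threshold and counts[i, j] > 0
        }
        keep.add(iupac.CONCRETE[int(np.argmax(freqs))])
        codes.append(iupac.SET_CODES[frozenset(keep)])
    return ConsensusSequence("".join(codes), inclusion_threshold, proportion)


def similarity_profile(
    cons: ConsensusSequence,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> SimilarityProfile:
    """Sliding-window similarity index 1/D over the consensus."""
    length = len(cons)
    if window_size < 1 or window_size > length:
        raise PrimervalError(
            f"window_size {window_size} invalid for consensus of length {length}"
        )
    if step < 1:
        raise ValueError("step must be >= 1")

    set_sizes = np.array([len(iupac.CODE_SETS[c]) for c in cons.codes], dtype=float)
    log_sizes = np.log(set_sizes)
    n_windows = (length - window_size) // step + 1
    starts = np.arange(n_windows) * step + 1

    cum_log = np.concatenate([[0.0], np.cumsum(log_sizes)])
    cum_prop = np.concatenate([[0.0], np.cumsum(cons.nongap_proportion)])
    i0 = starts - 1
    degeneration = np.exp(cum_log[i0 + window_size] - cum_log[i0])
    # exact integer D for windows small enough to matter numerically
    degeneration = np.round(degeneration)
    index = 1.0 / degeneration
    proportion = (cum_prop[i0 + window_size] - cum_prop[i0]) / window_size
    return SimilarityProfile(window_size, step, starts, degeneration, index, proportion)


def profile_over_interval(
    profile: SimilarityProfile, interval: tuple[int, int]
) -> tuple[float, float, float]:
    """(min index, max index, mean proportion) of windows overlapping an interval."""
    lo, hi = interval
    ends = profile.window_start + profile.window_size - 1
    mask = (profile.window_start <= hi) & (ends >= lo)
    if not mask.any():
        raise PrimervalError(f"no profile window overlaps interval {interval}")
    return (
        float(profile.index[mask].min()),
        float(profile.index[mask].max()),
        float(profile.proportion[mask].mean()),
    )


def window_degeneracy(cons: ConsensusSequence, interval: tuple[int, int]) -> int:
    """Exact D for one consensus interval (1-based inclusive)."""
    lo, hi = interval
    return math.prod(len(iupac.CODE_SETS[c]) for c in cons.codes[lo - 1 : hi])
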