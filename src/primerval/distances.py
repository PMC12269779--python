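"""Kimura two-parameter distances and barcoding-gap analysis.

The K80 model distinguishes transitions (A<->G, C<->T; proportion P of
compared sites) from transversions (proportion Q) and estimates the
substitutions-per-site distance

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)).

Distances are computed with pairwise deletion: only columns where both
sequences carry a concrete A/C/G/T base are compared, and a pair is
invalid (distance undefined) when the log argument is non-positive
(saturation) or fewer than ``min_overlap`` sites remain.

Pairs are partitioned by species label into intraspecific and
interspecific sets; the barcoding gap is the smallest interspecific
distance minus the largest intraspecific distance, positive when the
two distributions are separated and species can be told apart by a
distance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import PrimervalError
from .model import AlignedSequenceSet

INTRA = "intra"
INTER = "inter"

DEFAULT_MIN_OVERLAP = 100
DEFAULT_BIN_WIDTH = 0.01

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def k80_distance(
    seq_a: str,
    seq_b: str,
    min_overlap: int = 1,
) -> tuple[float, float, float, bool]:
    """(P, Q, distance, valid) between two equal-length gapped sequences."""
    if len(seq_a) != len(seq_b):
        raise PrimervalError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a = _encode(seq_a)
    b = _encode(seq_b)
    return _k80_from_codes(a, b, min_overlap)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().replace("U", "T").encode(), dtype="S1")
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == base.encode()] = code
    return out


def _k80_from_codes(a: np.ndarray, b: np.ndarray, min_overlap: int):
    both = (a >= 0) & (b >= 0)
    n = int(both.sum())
    if n < max(min_overlap, 1):
        return (float("nan"), float("nan"), float("nan"), False)
    aa = a[both]
    bb = b[both]
    diff = aa != bb
    # A=0,G=2 even; C=1,T=3 odd: same parity + different base = transition
    transition = diff & ((aa & 1) == (bb & 1))
    p = float(transition.sum()) / n
    q = float(diff.sum() - transition.sum()) / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return (p, q, float("nan"), False)
    d = -0.5 * np.log(w1 * np.sqrt(w2))
    return (p, q, float(d), True)


def distance_matrix(
    aln: AlignedSequenceSet,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """All unordered pairwise K80 distances with intra/inter classes.

    Invalid (saturated or low-overlap) pairs are retained with
    ``valid=False`` and an unset distance.
    """
    if len(aln) < 2:
        raise PrimervalError("need >= 2 records for pairwise distances")
    codes = np.stack([_encode(rec.sequence) for rec in aln])
    ids = [rec.sequence_id for rec in aln]
    species = aln.species_labels
    rows = []
    n = len(aln)
    for i in range(n - 1):
        ai = codes[i]
        for j in range(i + 1, n):
            p, q, d, valid = _k80_from_codes(ai, codes[j], min_overlap)
            rows.append(
                (
                    ids[i],
                    ids[j],
                    INTRA if species[i] == species[j] else INTER,
                    p,
                    q,
                    d,
                    valid,
                )
            )
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "comparison", "P", "Q", "distance", "valid"]
    )


@dataclass(frozen=True)
class BarcodingGapResult:
    max_intra: float
    min_inter: float
    gap: float  # min_inter - max_intra; negative when the classes overlap
    bin_width: float
    bin_edges: np.ndarray
    intra_histogram: np.ndarray
    inter_histogram: np.ndarray
    n_intra: int
    n_inter: int
    n_invalid: int  # saturated / low-overlap pairs excluded from the stats

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "intra": self.intra_histogram,
                "inter": self.inter_histogram,
            }
        )

    def summary(self) -> dict:
        return {
            "max_intra": self.max_intra,
            "min_inter": self.min_inter,
            "gap": self.gap,
            "n_intra_pairs": self.n_intra,
            "n_inter_pairs": self.n_inter,
            "n_invalid_pairs": self.n_invalid,
            "bin_width": self.bin_width,
        }


def gap_statistics(
    dists: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BarcodingGapResult:
    """Barcoding-gap statistics and frequency histograms.

    Raises naming the missing class when no valid intra- or
    interspecific pair exists (e.g. a single-species input).
    """
    valid = dists[dists["valid"]]
    intra = valid.loc[valid["comparison"] == INTRA, "distance"].to_numpy()
    inter = valid.loc[valid["comparison"] == INTER, "distance"].to_numpy()
    if intra.size == 0:
        raise PrimervalError("no valid intraspecific pairs (single sequence per species?)")
    if inter.size == 0:
        raise PrimervalError("no valid interspecific pairs (single-species input?)")

    max_intra = float(intra.max())
    min_inter = float(inter.min())
    top = max(intra.max(), inter.max())
    # one bin past the largest distance so the top value is always binned
    n_bins = int(np.floor(top / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    intra_hist, _ = np.histogram(intra, bins=edges)
    inter_hist, _ = np.histogram(inter, bins=edges)
    return BarcodingGapResult(
        max_intra=max_intra,
        min_inter=min_inter,
        gap=min_inter - max_intra,
        bin_width=bin_width,
        bin_edges=edges,
        intra_histogram=intra_hist,
        inter_histogram=inter_hist,
        n_intra=int(intra.size),
        n_inter=int(inter.size),
        n_invalid=int((~dists["valid"]).sum()),
    )
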