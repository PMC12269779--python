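"""Position- and type-weighted mismatch penalty scoring.

Each primer/template comparison is scored as a weighted sum over primer
positions: a mismatch near the 3' terminus (the extension end) costs
far more than the same mismatch near the 5' end, and the cost also
depends on which bases are mispaired.  Degenerate codes receive
fractional credit: the per-position penalty is the mean over all
ordered concrete (primer base, template base) combinations, so a wobble
position that partially matches the template scores between a full
match and a full mismatch.

Forward and reverse scores are summed per sequence and classified
against a threshold (default 150, the midpoint of the empirical
100-200 zone separating amplification success from failure):
strictly below the threshold = "Working", at or above = "Failed",
unevaluable sites = "Missing".

The packaged default weight tables are a synthetic stand-in (see
``data/penalty_matrices_synthetic_v1.yaml``); every operation accepts a
:class:`PenaltyMatrices` so transcriptions of published tables can be
used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import iupac
from .exceptions import PrimervalError
from .model import FORWARD, AlignedSequenceSet, DegeneratePrimer, PrimerPair
from .binding import _reverse_complement_gapped, locate_primer
from .similarity import ConsensusSequence, build_consensus

WORKING = "Working"
FAILED = "Failed"
MISSING = "Missing"

DEFAULT_THRESHOLD = 150.0
_TEMPLATE_COLUMNS = ("A", "C", "G", "T", "-", "N")


@dataclass(frozen=True)
class PenaltyMatrices:
    """Mismatch weight tables.

    position_factor: multipliers indexed by distance from the 3'
    terminus (entry 0 = terminal base); positions beyond the vector
    reuse the last entry.  type_factor maps ordered (primer base,
    template base) pairs — template in {A,C,G,T,-,N} — to weights, zero
    on matching concrete pairs.  adjacency_factor multiplies the
    penalty of a mismatch whose neighbour also mismatches (1 = no
    adjacency penalty).  gap_as_missing / n_as_missing switch template
    gaps / Ns from being scored via their table columns to making the
    whole site unevaluable.
    """

    position_factor: tuple[float, ...]
    type_factor: dict[tuple[str, str], float]
    adjacency_factor: float = 1.0
    gap_as_missing: bool = False
    n_as_missing: bool = False
    version: str = "custom"

    def __post_init__(self) -> None:
        pf = np.asarray(self.position_factor, dtype=float)
        if pf.size == 0 or (pf < 0).any():
            raise ValueError("position_factor must be non-empty and non-negative")
        if (np.diff(pf) > 1e-12).any():
            raise ValueError("position_factor must be non-increasing from the 3' terminus")
        for x in iupac.CONCRETE:
            for y in _TEMPLATE_COLUMNS:
                v = self.type_factor.get((x, y))
                if v is None:
                    raise ValueError(f"type_factor missing pair ({x}, {y})")
                if v < 0:
                    raise ValueError(f"type_factor({x},{y}) negative")
            if self.type_factor[(x, x)] != 0:
                raise ValueError("type_factor must be 0 on matching concrete pairs")

    def position(self, distance_from_3prime: int) -> float:
        """Multiplier for a position at 1-based distance from the 3' terminus."""
        i = min(distance_from_3prime, len(self.position_factor)) - 1
        return self.position_factor[i]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PenaltyMatrices":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: dict) -> "PenaltyMatrices":
        tf = {
            (x, str(y)): float(v)
            for x, row in doc["type_factor"].items()
            for y, v in row.items()
        }
        return cls(
            position_factor=tuple(float(v) for v in doc["position_factor"]),
            type_factor=tf,
            adjacency_factor=float(doc.get("adjacency_factor", 1.0)),
            gap_as_missing=bool(doc.get("gap_as_missing", False)),
            n_as_missing=bool(doc.get("n_as_missing", False)),
            version=str(doc.get("version", "custom")),
        )

    @classmethod
    def default(cls) -> "PenaltyMatrices":
        """The packaged synthetic_v1 tables."""
        ref = resources.files("primerval.data") / "penalty_matrices_synthetic_v1.yaml"
        return cls._from_doc(yaml.safe_load(ref.read_text()))

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "version": self.version,
            "position_factor": list(self.position_factor),
            "type_factor": {
                x: {y: self.type_factor[(x, y)] for y in _TEMPLATE_COLUMNS}
                for x in iupac.CONCRETE
            },
            "adjacency_factor": self.adjacency_factor,
            "gap_as_missing": self.gap_as_missing,
            "n_as_missing": self.n_as_missing,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def uniform_matrices(
    mismatch: float = 1.0,
    position: float = 1.0,
    length: int = 1,
    **kwargs,
) -> PenaltyMatrices:
    """Flat matrices (every mismatch the same weight) for hand-computable scores."""
    tf = {
        (x, y): (0.0 if x == y else mismatch)
        for x in iupac.CONCRETE
        for y in _TEMPLATE_COLUMNS
    }
    return PenaltyMatrices(
        position_factor=(position,) * length, type_factor=tf, version="uniform", **kwargs
    )


def pair_penalty(primer_code: str, template_code: str, matrices: PenaltyMatrices) -> float:
    """Unweighted penalty of one primer code against one template code.

    Mean over ordered concrete combinations; template gap and N are
    scored through their dedicated table columns.
    """
    if primer_code == iupac.GAP:
        raise PrimervalError("primer positions cannot be gaps")
    xs = sorted(iupac.CODE_SETS[primer_code])
    if template_code in ("-", "N"):
        return float(np.mean([matrices.type_factor[(x, template_code)] for x in xs]))
    ys = sorted(iupac.CODE_SETS[template_code])
    vals = [
        0.0 if x == y else matrices.type_factor[(x, y)] for x in xs for y in ys
    ]
    return float(np.mean(vals))


def primer_penalty(
    primer: DegeneratePrimer,
    template_site: str,
    matrices: PenaltyMatrices,
) -> tuple[float, bool]:
    """(score, missing) for one primer against its plus-strand site.

    Reverse primers are evaluated in their own orientation against the
    reverse-complemented site; position weights always count from the
    primer's 3' terminus.  A site is missing when gaps/Ns are flagged
    as missing by the matrices, or when it is entirely gaps.
    """
    site = iupac.normalize(template_site, allow_gap=True, context="template site")
    if len(site) != primer.length:
        raise PrimervalError(
            f"template site length {len(site)} != primer length {primer.length}"
        )
    if primer.orientation != FORWARD:
        site = _reverse_complement_gapped(site)

    if all(c == iupac.GAP for c in site):
        return (float("nan"), True)
    if matrices.gap_as_missing and iupac.GAP in site:
        return (float("nan"), True)
    if matrices.n_as_missing and "N" in site:
        return (float("nan"), True)

    n = primer.length
    penalties = np.array(
        [pair_penalty(p, t, matrices) for p, t in zip(primer.sequence, site)]
    )
    mism = penalties > 0
    score = 0.0
    for i in range(n):
        if penalties[i] == 0:
            continue
        adjacent = (i > 0 and mism[i - 1]) or (i < n - 1 and mism[i + 1])
        factor = matrices.adjacency_factor if adjacent else 1.0
        score += matrices.position(n - i) * penalties[i] * factor
    return (score, False)


def evaluate_penalties(
    aln: AlignedSequenceSet,
    pair: PrimerPair,
    matrices: PenaltyMatrices | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    consensus: ConsensusSequence | None = None,
) -> pd.DataFrame:
    """Score every record against both primers of a pair and classify.

    Returns a frame with per-sequence forward/reverse/combined scores
    and the Working/Failed/Missing class at ``threshold``.
    """
    if len(aln) == 0:
        raise PrimervalError("empty alignment")
    if matrices is None:
        matrices = PenaltyMatrices.default()
    fwd_site = pair.forward_site
    rev_site = pair.reverse_site
    if fwd_site is None or rev_site is None:
        if consensus is None:
            consensus = build_consensus(aln)
        if fwd_site is None:
            fwd_site = locate_primer(pair.forward, consensus)
        if rev_site is None:
            rev_site = locate_primer(pair.reverse, consensus)

    rows = []
    for rec in aln:
        fscore, fmiss = primer_penalty(pair.forward, aln.site(rec, fwd_site), matrices)
        rscore, rmiss = primer_penalty(pair.reverse, aln.site(rec, rev_site), matrices)
        rows.append(
            {
                "sequence_id": rec.sequence_id,
                "species": rec.species,
                "taxon": rec.taxon,
                "forward_score": fscore,
                "reverse_score": rscore,
                "missing": fmiss or rmiss,
            }
        )
    return classify(pd.DataFrame(rows), threshold=threshold)


def classify(scores: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Attach combined score and Working/Failed/Missing class.

    Working requires combined strictly below the threshold; a combined
    score exactly at the threshold is Failed.  Missing when either
    direction could not be scored.
    """
    if len(scores) == 0:
        raise PrimervalError("no scores to classify")
    out = scores.copy()
    if "missing" not in out:
        out["missing"] = out["forward_score"].isna() | out["reverse_score"].isna()
    out["combined"] = out["forward_score"] + out["reverse_score"]
    out["classification"] = np.where(
        out["missing"],
        MISSING,
        np.where(out["combined"] < threshold, WORKING, FAILED),
    )
    return out


def classification_table(results: pd.DataFrame, by: str = "taxon") -> pd.DataFrame:
    """Per-group Working/Failed/Missing counts and percentages.

    Percentages are over all sequences of the group and printed to two
    decimals; the three classes partition each group, so the
    percentages sum to 100 up to rounding.
    """
    rows = []
    for group, sub in results.groupby(by, sort=False):
        total = len(sub)
        counts = sub["classification"].value_counts()
        row = {by: group, "total": total}
        for cls in (WORKING, FAILED, MISSING):
            n = int(counts.get(cls, 0))
            row[cls.lower()] = n
            row[f"{cls.lower()}_pct"] = round(100.0 * n / total, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def score_distribution(results: pd.DataFrame, by: str = "taxon") -> pd.DataFrame:
    """Median and quartiles per group per primer direction (box-plot data)."""
    if len(results) == 0:
        raise PrimervalError("no scores")
    long = results.melt(
        id_vars=[by],
        value_vars=["forward_score", "reverse_score"],
        var_name="direction",
        value_name="score",
    ).dropna(subset=["score"])
    long["direction"] = long["direction"].str.replace("_score", "", regex=False)
    agg = (
        long.groupby([by, "direction"], sort=False)["score"]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            n="size",
        )
        .reset_index()
    )
    return agg
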