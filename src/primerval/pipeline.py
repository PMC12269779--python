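"""Orchestration of the full primer-validation workflow.

One :class:`ValidationConfig` drives conservation profiling, binding
analysis, penalty classification, the mixed-model primer comparison
(when two pairs are supplied) and the barcoding-gap analysis on the
target group, writing per-sequence TSVs, summary tables, JSON blocks
and a run manifest into an output directory.  Every number in the
summary tables is recomputable from the emitted per-sequence files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, binding, distances, glmm, penalty, published, similarity
from .exceptions import PrimervalError
from .io import read_aligned_fasta
from .model import AlignedSequenceSet, PrimerPair

logger = logging.getLogger("primerval")


@dataclass
class ValidationConfig:
    target_alignment: Path
    nontarget_alignments: dict[str, Path] = field(default_factory=dict)  # taxon -> path
    pairs: dict[str, PrimerPair] = field(default_factory=lambda: dict(published.PAIRS))
    species_map: Path | None = None
    binding_params: binding.BindingParameters = field(default_factory=binding.BindingParameters)
    penalty_matrices: penalty.PenaltyMatrices | None = None
    threshold: float = penalty.DEFAULT_THRESHOLD
    glmm_outcome: str = "binding"  # "binding" or "penalty"
    inclusion_threshold: float = similarity.DEFAULT_INCLUSION_THRESHOLD
    window_size: int = similarity.DEFAULT_WINDOW
    step: int = similarity.DEFAULT_STEP
    min_overlap: int = distances.DEFAULT_MIN_OVERLAP
    bin_width: float = distances.DEFAULT_BIN_WIDTH
    run_gap: bool = True
    make_plots: bool = False
    outdir: Path = Path("primerval_out")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ValidationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        pairs: dict[str, PrimerPair] = {}
        for name, entry in doc.get("pairs", {}).items():
            primers = {p["orientation"]: p for p in entry["primers"]}
            from .model import DegeneratePrimer

            pairs[name] = PrimerPair(
                DegeneratePrimer(primers["forward"]["name"], primers["forward"]["sequence"], "forward"),
                DegeneratePrimer(primers["reverse"]["name"], primers["reverse"]["sequence"], "reverse"),
                forward_site=tuple(entry["forward_site"]) if entry.get("forward_site") else None,
                reverse_site=tuple(entry["reverse_site"]) if entry.get("reverse_site") else None,
                expected_amplicon=entry.get("expected_amplicon"),
            )
        matrices = None
        if doc.get("penalty_matrices"):
            matrices = penalty.PenaltyMatrices.from_yaml(doc["penalty_matrices"])
        bp = doc.get("binding", {})
        return cls(
            target_alignment=Path(doc["target_alignment"]),
            nontarget_alignments={k: Path(v) for k, v in doc.get("nontarget_alignments", {}).items()},
            pairs=pairs or dict(published.PAIRS),
            species_map=Path(doc["species_map"]) if doc.get("species_map") else None,
            binding_params=binding.BindingParameters(
                max_total_mismatch=bp.get("max_total_mismatch", 3),
                three_prime_window=bp.get("three_prime_window", 2),
                max_three_prime_mismatch=bp.get("max_three_prime_mismatch", 0),
                missing_policy=bp.get("missing_policy", binding.MISSING_IF_GAP),
            ),
            penalty_matrices=matrices,
            threshold=doc.get("threshold", penalty.DEFAULT_THRESHOLD),
            glmm_outcome=doc.get("glmm_outcome", "binding"),
            run_gap=doc.get("run_gap", True),
            make_plots=doc.get("make_plots", False),
            outdir=Path(doc.get("outdir", "primerval_out")),
        )


def run_validation(config: ValidationConfig) -> dict:
    """Run every stage and write the report bundle; returns a result dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(levelname)s %(message)s")

    target = read_aligned_fasta(config.target_alignment, config.species_map, default_taxon="target")
    groups: dict[str, AlignedSequenceSet] = {"target": target}
    for taxon, path in config.nontarget_alignments.items():
        groups[taxon] = read_aligned_fasta(path, default_taxon=taxon)

    matrices = config.penalty_matrices or penalty.PenaltyMatrices.default()
    results: dict = {"stages": {}}

    # --- conservation profile (target group) -----------------------------
    stage = "similarity"
    try:
        cons = similarity.build_consensus(target, config.inclusion_threshold)
        profile = similarity.similarity_profile(cons, config.window_size, config.step)
        profile.to_frame().to_csv(out / "similarity_profile.tsv", sep="\t", index=False)
        results["stages"][stage] = {"n_windows": int(profile.window_start.size)}
        logger.info("similarity profile: %d windows", profile.window_start.size)
    except PrimervalError as exc:
        raise PrimervalError(f"[{stage}] {exc}") from exc

    # --- binding + penalty per pair per group ----------------------------
    binding_details: dict[str, pd.DataFrame] = {}
    penalty_details: dict[str, pd.DataFrame] = {}
    summaries = []
    class_tables = []
    score_tables = []
    sites_used: dict[str, dict[str, tuple[int, int]]] = {}
    for pair_name, pair in config.pairs.items():
        for taxon, aln in groups.items():
            label = f"{pair_name}:{taxon}"
            try:
                bres = binding.evaluate_pair(aln, pair, config.binding_params,
                                             consensus=cons if taxon == "target" else None)
                pres = penalty.evaluate_penalties(
                    aln, pair, matrices, config.threshold,
                    consensus=cons if taxon == "target" else None,
                )
            except PrimervalError as exc:
                raise PrimervalError(f"[binding/penalty {label}] {exc}") from exc
            bres.detail.insert(0, "primer_pair", pair_name)
            pres.insert(0, "primer_pair", pair_name)
            binding_details.setdefault(pair_name, pd.DataFrame())
            binding_details[pair_name] = pd.concat(
                [binding_details[pair_name], bres.detail], ignore_index=True
            )
            penalty_details.setdefault(pair_name, pd.DataFrame())
            penalty_details[pair_name] = pd.concat(
                [penalty_details[pair_name], pres], ignore_index=True
            )
            summary = bres.summary_table()
            summary.insert(0, "taxon", taxon)
            summary.insert(0, "primer_pair", pair_name)
            summaries.append(summary)
            ct = penalty.classification_table(pres, by="taxon")
            ct.insert(0, "primer_pair", pair_name)
            class_tables.append(ct)
            sd = penalty.score_distribution(pres, by="taxon")
            sd.insert(0, "primer_pair", pair_name)
            score_tables.append(sd)
            if taxon == "target":
                sites_used[pair_name] = {
                    "forward": bres.forward_site,
                    "reverse": bres.reverse_site,
                }

    for pair_name in config.pairs:
        binding_details[pair_name].to_csv(
            out / f"binding_per_sequence_{pair_name}.tsv", sep="\t", index=False
        )
        penalty_details[pair_name].to_csv(
            out / f"penalty_per_sequence_{pair_name}.tsv", sep="\t", index=False
        )
    pd.concat(summaries, ignore_index=True).to_csv(out / "binding_summary.tsv", sep="\t", index=False)
    pd.concat(class_tables, ignore_index=True).to_csv(
        out / "classification_summary.tsv", sep="\t", index=False
    )
    pd.concat(score_tables, ignore_index=True).to_csv(
        out / "score_distribution.tsv", sep="\t", index=False
    )
    results["binding_summary"] = pd.concat(summaries, ignore_index=True)
    results["classification_summary"] = pd.concat(class_tables, ignore_index=True)
    results["sites"] = sites_used

    # --- mixed model (two pairs) -----------------------------------------
    if len(config.pairs) == 2:
        ref_name, imp_name = list(config.pairs)
        try:
            target_mask = lambda df: df["taxon"] == "target"
            if config.glmm_outcome == "binding":
                ref_df = binding_details[ref_name][target_mask(binding_details[ref_name])]
                imp_df = binding_details[imp_name][target_mask(binding_details[imp_name])]
            else:
                ref_df = penalty_details[ref_name][target_mask(penalty_details[ref_name])]
                imp_df = penalty_details[imp_name][target_mask(penalty_details[imp_name])]
            records = glmm.build_records(ref_df, imp_df, outcome=config.glmm_outcome)
            fit = glmm.fit_glmm(records)
            (out / "glmm.json").write_text(fit.to_json())
            results["glmm"] = fit
            logger.info(
                "GLMM %s vs %s: effect %.4f (SE %.4f), OR %.2f",
                imp_name, ref_name, fit.effect, fit.effect_se, fit.odds_ratio,
            )
        except PrimervalError as exc:
            raise PrimervalError(f"[glmm] {exc}") from exc

    # --- barcoding gap (target only) -------------------------------------
    if config.run_gap:
        try:
            dists = distances.distance_matrix(target, config.min_overlap)
            gap = distances.gap_statistics(dists, config.bin_width)
            dists.to_csv(out / "distances.tsv", sep="\t", index=False)
            gap.histogram_frame().to_csv(out / "gap_histogram.tsv", sep="\t", index=False)
            (out / "gap_summary.json").write_text(json.dumps(gap.summary(), indent=2))
            results["gap"] = gap
            logger.info("barcoding gap: %.4f", gap.gap)
        except PrimervalError as exc:
            raise PrimervalError(f"[gap] {exc}") from exc

    if config.make_plots:
        from . import plotting

        plotting.plot_similarity_profile(
            profile, out / "similarity_profile.png",
            {f"{p}_{d}": s for p, ds in sites_used.items() for d, s in ds.items()},
        )
        if config.run_gap:
            plotting.plot_barcoding_gap(results["gap"], out / "barcoding_gap.png")

    _write_manifest(config, out)
    return results


def _write_manifest(config: ValidationConfig, out: Path) -> None:
    def file_hash(path: Path) -> str | None:
        try:
            return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        except OSError:
            return None

    manifest = {
        "primerval_version": __version__,
        "target_alignment": str(config.target_alignment),
        "target_alignment_sha256": file_hash(config.target_alignment),
        "nontarget_alignments": {
            k: {"path": str(v), "sha256": file_hash(v)}
            for k, v in config.nontarget_alignments.items()
        },
        "pairs": {
            name: {
                "forward": p.forward.sequence,
                "reverse": p.reverse.sequence,
                "forward_site": p.forward_site,
                "reverse_site": p.reverse_site,
            }
            for name, p in config.pairs.items()
        },
        "binding_params": {
            "max_total_mismatch": config.binding_params.max_total_mismatch,
            "three_prime_window": config.binding_params.three_prime_window,
            "max_three_prime_mismatch": config.binding_params.max_three_prime_mismatch,
            "missing_policy": config.binding_params.missing_policy,
        },
        "threshold": config.threshold,
        "glmm_outcome": config.glmm_outcome,
        "penalty_matrices_version": (config.penalty_matrices or penalty.PenaltyMatrices.default()).version,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
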