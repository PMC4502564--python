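"""End-to-end orchestration: normalize -> filter -> date -> classify -> stats.

Each stage logs its exclusions with a reason code, and the run manifest
accounts for every record: input = output + excluded, per stage. Given the
same inputs, config and seed, a run is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import classify_dataset, cutoff_sensitivity, species_pair_key
from .config import PipelineConfig
from .expression import filter_expressed, quantile_normalize, relative_profile, tissue_specificity
from .io import Bundle, load_bundle, validate_inputs
from .phylogeny import assign_parent_child, infer_duplication_branch
from .stats import (
    conserved_proportion_by_pair,
    fit_linear_regression,
    highest_tissue_enrichment,
    specificity_comparison,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "validate_inputs"]


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage it occurred in."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _checksums(indir: Path) -> dict[str, str]:
    sums = {}
    for path in sorted(indir.rglob("*")):
        if path.is_file():
            sums[str(path.relative_to(indir))] = hashlib.sha256(path.read_bytes()).hexdigest()
    return sums


def run_pipeline(
    indir: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage on an input bundle and write the output tables.

    Outputs in ``outdir``: dating.tsv, cutoffs.tsv, classification.tsv,
    exclusions.tsv, conservation_by_pair.tsv, regression.tsv,
    specificity.tsv, specificity_tests.tsv, enrichment.tsv,
    cutoff_sensitivity.tsv and manifest.json. Returns the manifest.
    """
    indir, outdir = Path(indir), Path(outdir)
    config = config or PipelineConfig()
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.__dict__ | {
            "species_priority": list(config.species_priority),
            "tissue_order": list(config.tissue_order),
        },
        "input_checksums": _checksums(indir),
        "stages": {},
    }

    # --- load & validate -------------------------------------------------
    report = validate_inputs(indir)
    if not report.ok:
        raise StageError("validate", "; ".join(report.errors))
    for warning in report.warnings:
        logger.info("[validate] %s", warning)
    bundle: Bundle = load_bundle(indir)
    manifest["stages"]["validate"] = {
        "n_matrices": len(bundle.matrices),
        "n_trios_in": len(bundle.trios),
        "warnings": report.warnings,
    }

    # --- normalize -------------------------------------------------------
    logger.info("[normalize] quantile-normalizing %d matrices", len(bundle.matrices))
    try:
        normalized_list = quantile_normalize(
            list(bundle.matrices.values()), per_species=config.per_species_normalization
        )
    except ValueError as exc:
        raise StageError("normalize", str(exc)) from exc
    matrices = {m.species: m for m in normalized_list}
    manifest["stages"]["normalize"] = {
        "pooled": not config.per_species_normalization,
        "n_samples": int(sum(len(m.tissue_labels) for m in matrices.values())),
    }

    # --- filter ----------------------------------------------------------
    expressed = {
        sp: filter_expressed(m, config.expression_threshold) for sp, m in matrices.items()
    }
    manifest["stages"]["filter"] = {
        sp: {"n_genes": len(m.gene_ids), "n_expressed": len(expressed[sp])}
        for sp, m in matrices.items()
    }

    # --- date & assign ---------------------------------------------------
    dating_rows = []
    if bundle.copy_number is not None:
        flags_by_family: dict[str, dict[str, bool]] = {}
        if bundle.alignment_flags is not None:
            for row in bundle.alignment_flags.itertuples(index=False):
                flags_by_family.setdefault(row.family_id, {})[row.copy_id] = bool(
                    row.aligns_to_outgroup
                )
        for family_id, group in bundle.copy_number.groupby("family_id", sort=True):
            pattern = dict(zip(group["species"], group["copy_number"].astype(int)))
            try:
                date = infer_duplication_branch(
                    pattern, bundle.tree, family_id, config.require_full_coverage
                )
            except ValueError as exc:
                raise StageError("date", str(exc)) from exc
            flags = flags_by_family.get(family_id)
            if flags is not None and len(flags) == 2:
                assignment = assign_parent_child(flags, family_id)
            else:
                assignment = None
            if not date.resolved:
                logger.debug("[date] %s: unresolved parsimony", family_id)
            if assignment is not None and not assignment.resolved:
                logger.debug("[date] %s: ambiguous parent/child", family_id)
            dating_rows.append(
                {
                    "family_id": family_id,
                    "origin_branch": date.origin_branch,
                    "resolved": date.resolved,
                    "parent": assignment.parent if assignment and assignment.resolved else "",
                    "child": assignment.child if assignment and assignment.resolved else "",
                }
            )
    dating = pd.DataFrame(
        dating_rows, columns=["family_id", "origin_branch", "resolved", "parent", "child"]
    )
    dating.to_csv(outdir / "dating.tsv", sep="\t", index=False)
    manifest["stages"]["date"] = {
        "n_families": len(dating),
        "n_resolved": int(dating["resolved"].sum()) if len(dating) else 0,
    }

    # --- baseline cutoffs & classification -------------------------------
    try:
        records, exclusions, cutoffs = classify_dataset(
            bundle.trios, matrices, bundle.orthologs, config
        )
    except ValueError as exc:
        raise StageError("classify", str(exc)) from exc
    records.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    exclusions.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "species_1": pair[0],
                "species_2": pair[1],
                "n_baseline": len(cut.baseline_distances),
                "median": cut.median,
                "siqr": cut.siqr,
                "cutoff": cut.cutoff,
            }
            for pair, cut in sorted(cutoffs.items())
        ]
    ).to_csv(outdir / "cutoffs.tsv", sep="\t", index=False)
    label_counts = Counter(records["label"])
    manifest["stages"]["classify"] = {
        "n_trios_in": len(bundle.trios),
        "n_classified": len(records),
        "n_excluded": len(exclusions),
        "exclusion_reasons": Counter(exclusions["reason"]).most_common(),
        "class_counts": dict(sorted(label_counts.items())),
    }
    if len(bundle.trios) != len(records) + len(exclusions):
        raise StageError("classify", "record accounting mismatch")

    sensitivity = cutoff_sensitivity(records, cutoffs, [0.5, 1.0, 1.5, 2.0]) if len(records) else pd.DataFrame()
    sensitivity.to_csv(outdir / "cutoff_sensitivity.tsv", sep="\t", index=False)

    # --- statistics ------------------------------------------------------
    if not bundle.ks_per_pair:
        raise StageError("stats", "missing input: ks.tsv")
    baselines = {pair: cut.baseline_distances for pair, cut in cutoffs.items()}
    cutoff_values = {pair: cut.cutoff for pair, cut in cutoffs.items()}
    try:
        by_pair = conserved_proportion_by_pair(
            records, bundle.ks_per_pair, baselines, cutoff_values, bundle.ka_per_pair or None
        )
    except ValueError as exc:
        raise StageError("stats", str(exc)) from exc
    by_pair.to_csv(outdir / "conservation_by_pair.tsv", sep="\t", index=False)

    regression_rows = []
    if len(by_pair) >= 3 and by_pair["ks_median"].nunique() >= 2:
        fit = fit_linear_regression(by_pair["ks_median"], by_pair["proportion_conserved"])
        regression_rows.append({"gene_set": "duplicates", **fit.__dict__})
        if "proportion_conserved_single_copy" in by_pair:
            fit_sc = fit_linear_regression(
                by_pair["ks_median"], by_pair["proportion_conserved_single_copy"]
            )
            regression_rows.append({"gene_set": "single_copy", **fit_sc.__dict__})
    else:
        logger.info("[stats] too few species pairs for the K_s regression")
    pd.DataFrame(
        regression_rows,
        columns=["gene_set", "slope", "intercept", "f_pvalue", "slope_t_pvalue", "n_points"],
    ).to_csv(outdir / "regression.tsv", sep="\t", index=False)

    specificity_frame, spec_scores = _specificity_scores(matrices, expressed)
    specificity_frame.to_csv(outdir / "specificity.tsv", sep="\t", index=False)

    single_copy_genes = _single_copy_gene_sets(bundle)
    single_scores = [
        spec_scores[(sp, g)][0]
        for sp, genes in single_copy_genes.items()
        for g in genes
        if (sp, g) in spec_scores
    ]

    group_scores, tissue_tables = _grouped_specificities(
        bundle, records, spec_scores, single_scores
    )
    if single_scores and all(len(v) for v in group_scores.values()) and group_scores:
        spec_tests = specificity_comparison(group_scores, single_scores)
    else:
        spec_tests = pd.DataFrame()
    spec_tests.to_csv(outdir / "specificity_tests.tsv", sep="\t", index=False)

    populated = {g: t for g, t in tissue_tables.items() if sum(t.values())}
    if len(populated) >= 2:
        enrichment = highest_tissue_enrichment(populated, list(config.tissue_order))
    else:
        enrichment = pd.DataFrame()
    enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    manifest["stages"]["stats"] = {
        "n_species_pairs": len(by_pair),
        "regressions": [r["gene_set"] for r in regression_rows],
        "n_specificity_groups": len(group_scores),
        "n_enrichment_tests": len(enrichment),
    }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _specificity_scores(matrices, expressed):
    """Tissue-specificity score (max relative expression) per expressed gene."""
    rows = []
    scores: dict[tuple[str, str], tuple[float, str]] = {}
    for sp, matrix in sorted(matrices.items()):
        expressed_set = set(expressed[sp])
        labels = tuple(matrix.tissue_labels)
        for gene in matrix.gene_ids:
            if gene not in expressed_set:
                continue
            row = matrix.row(gene)
            if row.sum() <= 0:
                continue
            call = tissue_specificity(relative_profile(row, labels, gene_id=gene))
            scores[(sp, gene)] = (call.max_proportion, call.top_tissue)
            rows.append(
                {
                    "gene_id": gene,
                    "species": sp,
                    "max_proportion": call.max_proportion,
                    "top_tissue": call.top_tissue,
                }
            )
    return (
        pd.DataFrame(rows, columns=["gene_id", "species", "max_proportion", "top_tissue"]),
        scores,
    )


def _single_copy_gene_sets(bundle: Bundle) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for (sp1, sp2), table in bundle.orthologs.items():
        sets.setdefault(sp1, set()).update(table["gene_1"])
        sets.setdefault(sp2, set()).update(table["gene_2"])
    return sets


def _grouped_specificities(bundle, records, spec_scores, single_scores):
    """Class x role specificity groups and highest-tissue count tables.

    Enrichment groups follow the figure-panel convention: "conserved" pools
    both copies of conserved pairs plus the non-diverged copy of
    neofunctionalized pairs; "neofunctionalized" is the diverged copies.
    """
    trio_index = bundle.trios.set_index("pair_id")
    group_scores: dict[str, list[float]] = {}
    tissue_tables: dict[str, Counter] = {
        "single_copy": Counter(),
        "outgroup": Counter(),
        "conserved": Counter(),
        "neofunctionalized": Counter(),
    }
    single_copy_sets = _single_copy_gene_sets(bundle)
    for sp, genes in single_copy_sets.items():
        for gene in genes:
            if (sp, gene) in spec_scores:
                tissue_tables["single_copy"][spec_scores[(sp, gene)][1]] += 1

    for rec in records.itertuples(index=False):
        trio = trio_index.loc[rec.pair_id]
        focal, outgroup_sp = rec.focal_species, rec.outgroup_species
        keyed = {
            "parent": (focal, trio["parent_gene"]),
            "child": (focal, trio["child_gene"]),
            "outgroup": (outgroup_sp, trio["outgroup_gene"]),
        }
        for role, key in keyed.items():
            if key not in spec_scores:
                continue
            score, top = spec_scores[key]
            group_scores.setdefault(f"{rec.label}:{role}", []).append(score)
            if role == "outgroup":
                tissue_tables["outgroup"][top] += 1
            elif rec.label == "CONSERVED":
                tissue_tables["conserved"][top] += 1
            elif rec.label == "NEOFUNC_PARENT":
                tissue_tables["neofunctionalized" if role == "parent" else "conserved"][top] += 1
            elif rec.label == "NEOFUNC_CHILD":
                tissue_tables["neofunctionalized" if role == "child" else "conserved"][top] += 1
    return group_scores, tissue_tables
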