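"""Expression-divergence classification of duplicate gene pairs.

For a duplicate pair with parent copy P and child copy C in a focal species,
and a single-copy ortholog O (the outgroup gene) in a closely related sister
species standing proxy for the ancestral gene, three Euclidean distances
between relative expression profiles are computed:

    E_PO  = d(P, O)        parent vs outgroup
    E_CO  = d(C, O)        child vs outgroup
    E_PCO = d(P+C, O)      combined parent+child output vs outgroup

A divergence cutoff is estimated per species pair from the distribution of
distances between single-copy orthologs in the two species (E_S1,S2): cutoff
= median + SIQR, with SIQR = (Q3 - Q1) / 2 chosen for robustness to outliers.
The rule table then assigns exactly one of five retention classes:

    CONSERVED       E_PO <= cut and E_CO <= cut
    NEOFUNC_PARENT  E_PO >  cut and E_CO <= cut
    NEOFUNC_CHILD   E_PO <= cut and E_CO >  cut
    SUBFUNC         E_PO >  cut and E_CO >  cut and E_PCO <= cut
    SPECIALIZED     E_PO >  cut and E_CO >  cut and E_PCO >  cut

Equality with the cutoff counts as NOT diverged. All comparisons are exact
floating-point <= / > with no epsilon, so results are deterministic given the
inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import CLASS_LABELS, PipelineConfig
from .expression import (
    ExpressionMatrix,
    RelativeProfile,
    filter_expressed,
    relative_profile,
    restrict_to_shared_tissues,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DivergenceCutoff",
    "DuplicateClassifier",
    "euclidean_distance",
    "baseline_distances",
    "divergence_cutoff",
    "classify_trio",
    "classify_dataset",
    "cutoff_sensitivity",
    "species_pair_key",
]


def species_pair_key(species_1: str, species_2: str) -> tuple[str, str]:
    """Canonical unordered key for a species pair."""
    if species_1 == species_2:
        raise ValueError("species pair must involve two distinct species")
    return tuple(sorted((species_1, species_2)))  # type: ignore[return-value]


@dataclass
class DivergenceCutoff:
    """Per-species-pair baseline distance summary and divergence cutoff."""

    species_pair: tuple[str, str]
    baseline_distances: np.ndarray
    median: float
    siqr: float
    cutoff: float


def euclidean_distance(p: RelativeProfile, q: RelativeProfile) -> float:
    """Euclidean distance between two relative expression profiles.

    Bounded by sqrt(2) for proportion vectors (attained by disjoint
    single-tissue profiles).
    """
    if tuple(p.tissue_labels) != tuple(q.tissue_labels):
        raise ValueError("mismatched tissue sets")
    return float(np.linalg.norm(p.proportions - q.proportions))


def baseline_distances(
    ortholog_pairs: Iterable[tuple[str, str]],
    matrix_1: ExpressionMatrix,
    matrix_2: ExpressionMatrix,
    threshold: float = 1.0,
) -> np.ndarray:
    """E_S1,S2 distances for single-copy ortholog pairs between two species.

    Pairs in which either gene fails the expression filter are skipped;
    profiles are restricted to the species pair's shared tissues and
    renormalized before the distance is taken. Output order follows input
    order of the surviving pairs.
    """
    expressed_1 = set(filter_expressed(matrix_1, threshold))
    expressed_2 = set(filter_expressed(matrix_2, threshold))
    distances: list[float] = []
    for gene_1, gene_2 in ortholog_pairs:
        if gene_1 not in expressed_1 or gene_2 not in expressed_2:
            continue
        row_1, row_2, shared = restrict_to_shared_tissues(
            matrix_1.row(gene_1),
            matrix_2.row(gene_2),
            matrix_1.tissue_labels,
            matrix_2.tissue_labels,
        )
        if row_1.sum() <= 0 or row_2.sum() <= 0:
            continue
        p = relative_profile(row_1, shared)
        q = relative_profile(row_2, shared)
        distances.append(euclidean_distance(p, q))
    if not distances:
        raise ValueError("empty baseline")
    return np.asarray(distances, dtype=float)


def divergence_cutoff(
    distances: Sequence[float] | np.ndarray,
    species_pair: tuple[str, str] = ("S1", "S2"),
    quantile_method: str = "linear",
    siqr_multiplier: float = 1.0,
) -> DivergenceCutoff:
    """Median + SIQR divergence cutoff from a baseline distance list.

    Quartiles use linear interpolation between order statistics by default;
    the convention is configurable because the subfunctionalized class is
    sensitive to the exact cutoff.
    """
    arr = np.asarray(distances, dtype=float)
    if arr.size == 0:
        raise ValueError("empty baseline")
    if np.any(arr < 0):
        raise ValueError("negative distance")
    median = float(np.median(arr))
    q1, q3 = (float(v) for v in np.quantile(arr, [0.25, 0.75], method=quantile_method))
    siqr = (q3 - q1) / 2.0
    return DivergenceCutoff(
        species_pair=species_pair,
        baseline_distances=arr,
        median=median,
        siqr=siqr,
        cutoff=median + siqr_multiplier * siqr,
    )


def classify_trio(e_po: float, e_co: float, e_pco: float, cutoff: float) -> str:
    """Apply the five-way rule table to one trio's distances.

    Exactly one label applies to any admissible input; equality with the
    cutoff counts as not diverged.
    """
    if e_po < 0 or e_co < 0 or e_pco < 0:
        raise ValueError("distances must be non-negative")
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    parent_diverged = e_po > cutoff
    child_diverged = e_co > cutoff
    if not parent_diverged and not child_diverged:
        return "CONSERVED"
    if parent_diverged and not child_diverged:
        return "NEOFUNC_PARENT"
    if not parent_diverged and child_diverged:
        return "NEOFUNC_CHILD"
    return "SUBFUNC" if e_pco <= cutoff else "SPECIALIZED"


class DuplicateClassifier(BaseEstimator):
    """Rule-based duplicate-pair classifier with an estimated divergence cutoff.

    ``fit`` takes the baseline E_S1,S2 distances of a species pair and
    estimates the divergence cutoff (median + ``siqr_multiplier`` * SIQR);
    ``predict`` maps rows of (E_PO, E_CO, E_PCO) to the five retention
    classes. The estimator is deterministic and composes with sklearn
    utilities (``get_params`` / ``set_params`` / ``clone``).

    Parameters
    ----------
    siqr_multiplier : float, default 1.0
        Scale on the SIQR term; larger values give a more stringent
        (conservative) divergence call.
    quantile_method : str, default "linear"
        Quantile convention passed to :func:`numpy.quantile`.

    Attributes
    ----------
    median_, siqr_, cutoff_ : float
        Baseline summary statistics estimated by ``fit``.
    classes_ : ndarray of str
        The five class labels.
    """

    def __init__(self, siqr_multiplier: float = 1.0, quantile_method: str = "linear"):
        self.siqr_multiplier = siqr_multiplier
        self.quantile_method = quantile_method

    def fit(self, X: Sequence[float] | np.ndarray, y=None) -> "DuplicateClassifier":
        X = np.asarray(X, dtype=float).ravel()
        summary = divergence_cutoff(
            X,
            quantile_method=self.quantile_method,
            siqr_multiplier=self.siqr_multiplier,
        )
        self.n_baseline_ = int(X.size)
        self.median_ = summary.median
        self.siqr_ = summary.siqr
        self.cutoff_ = summary.cutoff
        self.classes_ = np.asarray(CLASS_LABELS)
        return self

    def predict(self, X: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
        if not hasattr(self, "cutoff_"):
            raise ValueError("DuplicateClassifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != 3:
            raise ValueError("expected columns (e_po, e_co, e_pco)")
        return np.asarray(
            [classify_trio(e_po, e_co, e_pco, self.cutoff_) for e_po, e_co, e_pco in X]
        )


def classify_dataset(
    trios: pd.DataFrame,
    matrices: Mapping[str, ExpressionMatrix],
    orthologs: Mapping[tuple[str, str], pd.DataFrame],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], DivergenceCutoff]]:
    """Classify every trio in a dataset against per-species-pair cutoffs.

    Parameters
    ----------
    trios : DataFrame
        Columns pair_id, focal_species, parent_gene, child_gene,
        outgroup_species, outgroup_gene.
    matrices : mapping species -> ExpressionMatrix
        Normalized absolute expression.
    orthologs : mapping (species, species) -> DataFrame
        Single-copy ortholog tables with columns gene_1, gene_2, where
        gene_1 belongs to the alphabetically first species of the key.
    config : PipelineConfig, optional

    Returns
    -------
    records : DataFrame
        pair_id, focal_species, outgroup_species, e_po, e_co, e_pco,
        cutoff_used, label — one row per surviving trio.
    exclusions : DataFrame
        pair_id, reason — trios dropped by the expression filter or for
        missing genes, with a logged reason.
    cutoffs : dict
        The per-species-pair DivergenceCutoff objects used.
    """
    config = config or PipelineConfig()
    threshold = config.expression_threshold

    expressed = {
        sp: set(filter_expressed(m, threshold)) for sp, m in matrices.items()
    }

    cutoffs: dict[tuple[str, str], DivergenceCutoff] = {}

    def cutoff_for(pair: tuple[str, str]) -> DivergenceCutoff:
        if pair not in cutoffs:
            if pair not in orthologs:
                raise ValueError(f"missing ortholog table / cutoff for species pair {pair}")
            table = orthologs[pair]
            dists = baseline_distances(
                zip(table["gene_1"], table["gene_2"]),
                matrices[pair[0]],
                matrices[pair[1]],
                threshold,
            )
            cutoffs[pair] = divergence_cutoff(
                dists,
                species_pair=pair,
                quantile_method=config.quantile_method,
                siqr_multiplier=config.siqr_multiplier,
            )
        return cutoffs[pair]

    records: list[dict] = []
    dropped: list[dict] = []

    def exclude(pair_id: str, reason: str) -> None:
        logger.debug("excluding trio %s: %s", pair_id, reason)
        dropped.append({"pair_id": pair_id, "reason": reason})

    for trio in trios.itertuples(index=False):
        focal, outgroup_sp = trio.focal_species, trio.outgroup_species
        if focal not in matrices or outgroup_sp not in matrices:
            exclude(trio.pair_id, "missing species matrix")
            continue
        focal_matrix, outgroup_matrix = matrices[focal], matrices[outgroup_sp]
        missing = [
            g
            for g, m in (
                (trio.parent_gene, focal_matrix),
                (trio.child_gene, focal_matrix),
                (trio.outgroup_gene, outgroup_matrix),
            )
            if g not in m.data.index
        ]
        if missing:
            exclude(trio.pair_id, f"gene(s) not in matrix: {','.join(missing)}")
            continue
        if trio.parent_gene not in expressed[focal]:
            exclude(trio.pair_id, "unexpressed parent")
            continue
        if trio.child_gene not in expressed[focal]:
            exclude(trio.pair_id, "unexpressed child")
            continue
        if trio.outgroup_gene not in expressed[outgroup_sp]:
            exclude(trio.pair_id, "unexpressed outgroup")
            continue

        pair = species_pair_key(focal, outgroup_sp)
        cut = cutoff_for(pair)

        parent_row = focal_matrix.row(trio.parent_gene)
        child_row = focal_matrix.row(trio.child_gene)
        outgroup_row = outgroup_matrix.row(trio.outgroup_gene)
        try:
            parent_shared, out_shared, shared = restrict_to_shared_tissues(
                parent_row,
                outgroup_row,
                focal_matrix.tissue_labels,
                outgroup_matrix.tissue_labels,
            )
            child_shared, _, _ = restrict_to_shared_tissues(
                child_row,
                outgroup_row,
                focal_matrix.tissue_labels,
                outgroup_matrix.tissue_labels,
            )
        except ValueError:
            exclude(trio.pair_id, "no shared tissues")
            continue
        if parent_shared.sum() <= 0 or child_shared.sum() <= 0 or out_shared.sum() <= 0:
            exclude(trio.pair_id, "zero expression on shared tissues")
            continue

        outgroup_profile = relative_profile(out_shared, shared)
        e_po = euclidean_distance(relative_profile(parent_shared, shared), outgroup_profile)
        e_co = euclidean_distance(relative_profile(child_shared, shared), outgroup_profile)
        e_pco = euclidean_distance(
            relative_profile(parent_shared + child_shared, shared), outgroup_profile
        )
        records.append(
            {
                "pair_id": trio.pair_id,
                "focal_species": focal,
                "outgroup_species": outgroup_sp,
                "e_po": e_po,
                "e_co": e_co,
                "e_pco": e_pco,
                "cutoff_used": cut.cutoff,
                "label": classify_trio(e_po, e_co, e_pco, cut.cutoff),
            }
        )

    record_columns = [
        "pair_id",
        "focal_species",
        "outgroup_species",
        "e_po",
        "e_co",
        "e_pco",
        "cutoff_used",
        "label",
    ]
    return (
        pd.DataFrame(records, columns=record_columns),
        pd.DataFrame(dropped, columns=["pair_id", "reason"]),
        cutoffs,
    )


def cutoff_sensitivity(
    records: pd.DataFrame,
    cutoffs: Mapping[tuple[str, str], DivergenceCutoff],
    multipliers: Sequence[float],
) -> pd.DataFrame:
    """Re-classify a dataset under scaled cutoffs (median + m * SIQR).

    Returns one row of five class counts per multiplier; the total count is
    constant across rows. More stringent (larger) multipliers can only move
    pairs toward the conserved class.
    """
    rows = []
    for m in multipliers:
        if m <= 0:
            raise ValueError("multipliers must be > 0")
        counts = dict.fromkeys(CLASS_LABELS, 0)
        for rec in records.itertuples(index=False):
            pair = species_pair_key(rec.focal_species, rec.outgroup_species)
            cut = cutoffs[pair]
            label = classify_trio(rec.e_po, rec.e_co, rec.e_pco, cut.median + m * cut.siqr)
            counts[label] += 1
        rows.append({"multiplier": m, **counts})
    return pd.DataFrame(rows)
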