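"""Multi-tissue expression handling: normalization, filtering, profiles.

Absolute FPKM-like values are quantile-normalized across samples, genes that
never reach the expression threshold are dropped, and each remaining gene is
summarized by its *relative* expression profile — the vector of per-tissue
proportions of total expression — which is the unit every downstream distance
is computed on. The maximum entry of a relative profile is the gene's
tissue-specificity score (1 = single-tissue, 1/n = uniform).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import CANONICAL_TISSUES

__all__ = [
    "ExpressionMatrix",
    "RelativeProfile",
    "TissueSpecificity",
    "QuantileNormalizer",
    "quantile_normalize",
    "filter_expressed",
    "relative_profile",
    "combine_profiles",
    "tissue_specificity",
    "restrict_to_shared_tissues",
]


@dataclass
class ExpressionMatrix:
    """Per-species gene x tissue matrix of non-negative absolute expression.

    ``data`` is indexed by gene id with one column per tissue sample; tissue
    labels must come from the canonical controlled vocabulary.
    """

    species: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError(f"duplicate gene ids in matrix for {self.species}")
        if self.data.columns.has_duplicates:
            raise ValueError(f"duplicate tissue labels in matrix for {self.species}")
        unknown = [t for t in self.data.columns if t not in CANONICAL_TISSUES]
        if unknown:
            raise ValueError(f"unknown tissue label(s) {unknown} for {self.species}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite expression value in matrix for {self.species}")
        if values.size and values.min() < 0:
            raise ValueError("negative expression")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissue_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def row(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path: str | Path, species: str | None = None) -> "ExpressionMatrix":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if species is None:
            species = path.name.split(".")[0]
        return cls(species=species, data=frame)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class RelativeProfile:
    """Per-gene vector of tissue proportions summing to 1."""

    tissue_labels: tuple[str, ...]
    proportions: np.ndarray
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if len(self.proportions) != len(self.tissue_labels):
            raise ValueError("proportions and tissue_labels length mismatch")
        if np.any(self.proportions < 0) or np.any(self.proportions > 1 + 1e-9):
            raise ValueError("proportions outside [0, 1]")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions do not sum to 1")


@dataclass
class TissueSpecificity:
    """Tissue-specificity call: the maximum relative expression and its tissue."""

    gene_id: str | None
    max_proportion: float
    top_tissue: str


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization of expression samples (columns).

    ``fit`` pools all provided samples into one normalization set and stores
    the reference distribution: for equal-length samples this is the per-rank
    mean of the samples' order statistics; samples of unequal length
    contribute through their quantile curves evaluated on a common grid.
    ``transform`` replaces each sample's values by the reference values at
    their ranks; ties within a sample receive the mean of the reference
    values at the tied ranks, so rank order (allowing ties) is preserved and
    the operation is idempotent.
    """

    def fit(self, X: Sequence[np.ndarray] | np.ndarray, y=None) -> "QuantileNormalizer":
        columns = _as_columns(X)
        if not columns or any(len(c) == 0 for c in columns):
            raise ValueError("no samples")
        for col in columns:
            if np.any(col < 0):
                raise ValueError("negative expression")
            if not np.all(np.isfinite(col)):
                raise ValueError("non-finite expression value")
        n_ref = max(len(c) for c in columns)
        grid = np.linspace(0.0, 1.0, n_ref) if n_ref > 1 else np.array([0.5])
        curves = [np.quantile(c, grid, method="linear") for c in columns]
        self.reference_ = np.mean(curves, axis=0)
        self.grid_ = grid
        self.n_samples_ = len(columns)
        return self

    def transform(self, X: Sequence[np.ndarray] | np.ndarray):
        if not hasattr(self, "reference_"):
            raise ValueError("QuantileNormalizer is not fitted")
        columns = _as_columns(X)
        out = [self._transform_column(np.asarray(c, dtype=float)) for c in columns]
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return np.column_stack(out)
        return out

    def _transform_column(self, col: np.ndarray) -> np.ndarray:
        if np.any(col < 0):
            raise ValueError("negative expression")
        n = len(col)
        if n == 0:
            raise ValueError("no samples")
        if n > 1:
            positions = np.linspace(0.0, 1.0, n)
        else:
            positions = np.array([0.5])
        # reference value for each rank of this sample
        rank_values = np.interp(positions, self.grid_, self.reference_)
        order = np.argsort(col, kind="stable")
        result = np.empty(n, dtype=float)
        sorted_vals = col[order]
        i = 0
        while i < n:  # average reference values across tied ranks
            j = i
            while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            result[order[i : j + 1]] = rank_values[i : j + 1].mean()
            i = j + 1
        return result


def quantile_normalize(
    matrices: Iterable[ExpressionMatrix] | ExpressionMatrix,
    per_species: bool = False,
) -> list[ExpressionMatrix]:
    """Quantile-normalize one or more expression matrices.

    Every tissue column of every matrix is treated as one sample. By default
    all samples of all matrices are pooled into a single normalization set;
    ``per_species=True`` normalizes each matrix independently.
    """
    if isinstance(matrices, ExpressionMatrix):
        matrices = [matrices]
    matrices = list(matrices)
    if not matrices or any(m.data.empty for m in matrices):
        raise ValueError("no samples")
    if per_species:
        return [quantile_normalize([m])[0] for m in matrices]

    columns: list[np.ndarray] = []
    for m in matrices:
        for t in m.tissue_labels:
            columns.append(m.data[t].to_numpy(dtype=float))
    normalizer = QuantileNormalizer().fit(columns)
    normalized = normalizer.transform(columns)

    out: list[ExpressionMatrix] = []
    k = 0
    for m in matrices:
        frame = m.data.copy()
        for t in m.tissue_labels:
            frame[t] = normalized[k]
            k += 1
        out.append(ExpressionMatrix(species=m.species, data=frame))
    return out


def filter_expressed(matrix: ExpressionMatrix, threshold: float = 1.0) -> list[str]:
    """Genes with expression >= ``threshold`` in at least one tissue.

    The boundary is inclusive: a gene whose largest value equals the
    threshold exactly counts as expressed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mask = (matrix.values >= threshold).any(axis=1)
    return [g for g, keep in zip(matrix.gene_ids, mask) if keep]


def relative_profile(
    absolute_row: Sequence[float] | np.ndarray,
    tissue_labels: Sequence[str],
    gene_id: str | None = None,
) -> RelativeProfile:
    """Convert absolute tissue expression to proportions of total expression."""
    row = np.asarray(absolute_row, dtype=float)
    if len(row) != len(tissue_labels):
        raise ValueError("row and tissue_labels length mismatch")
    if np.any(row < 0):
        raise ValueError("negative expression")
    total = row.sum()
    if total <= 0:
        raise ValueError("zero total expression")
    return RelativeProfile(
        tissue_labels=tuple(tissue_labels), proportions=row / total, gene_id=gene_id
    )


def combine_profiles(
    parent_row: Sequence[float] | np.ndarray,
    child_row: Sequence[float] | np.ndarray,
    tissue_labels: Sequence[str],
    gene_id: str | None = None,
) -> RelativeProfile:
    """Relative profile of the combined parent+child expression output.

    Per-tissue absolute values of the two copies are summed before
    conversion, so the combined profile represents the total transcriptional
    output of the duplicate pair — the proxy for the ancestral single gene.
    """
    parent = np.asarray(parent_row, dtype=float)
    child = np.asarray(child_row, dtype=float)
    if parent.shape != child.shape or len(parent) != len(tissue_labels):
        raise ValueError("misaligned tissue sets")
    return relative_profile(parent + child, tissue_labels, gene_id=gene_id)


def tissue_specificity(profile: RelativeProfile) -> TissueSpecificity:
    """Tissue specificity = the profile's maximum proportion; ties break to
    the earliest tissue in the profile's (canonical) order."""
    idx = int(np.argmax(profile.proportions))
    return TissueSpecificity(
        gene_id=profile.gene_id,
        max_proportion=float(profile.proportions[idx]),
        top_tissue=profile.tissue_labels[idx],
    )


def restrict_to_shared_tissues(
    row_a: Sequence[float] | np.ndarray,
    row_b: Sequence[float] | np.ndarray,
    labels_a: Sequence[str],
    labels_b: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Restrict two absolute rows to their shared tissues.

    Returns the aligned restricted rows and the shared label list (ordered as
    in ``labels_a``). Relative profiles must be recomputed on the restricted
    rows; this renormalization is what makes cross-species comparisons with
    unequal tissue panels well defined.
    """
    row_a = np.asarray(row_a, dtype=float)
    row_b = np.asarray(row_b, dtype=float)
    set_b = set(labels_b)
    shared = tuple(t for t in labels_a if t in set_b)
    if not shared:
        raise ValueError("no shared tissues")
    index_a = {t: i for i, t in enumerate(labels_a)}
    index_b = {t: i for i, t in enumerate(labels_b)}
    a = np.array([row_a[index_a[t]] for t in shared], dtype=float)
    b = np.array([row_b[index_b[t]] for t in shared], dtype=float)
    return a, b, shared


def _as_columns(X) -> list[np.ndarray]:
    if isinstance(X, np.ndarray):
        if X.ndim == 1:
            return [np.asarray(X, dtype=float)]
        if X.ndim == 2:
            return [np.asarray(X[:, j], dtype=float) for j in range(X.shape[1])]
        raise ValueError("expected a 1-D or 2-D array of samples")
    return [np.asarray(c, dtype=float) for c in X]
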