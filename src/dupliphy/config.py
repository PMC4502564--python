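"""Shared configuration: tissue vocabulary, species priority, pipeline settings.

The controlled tissue vocabulary covers the 11 tissue samples used to build
spatial expression profiles (five somatic tissues split by sex, plus testis).
Argmax ties in tissue-specificity calls are broken by this canonical order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

CANONICAL_TISSUES: tuple[str, ...] = (
    "cerebrum-F",
    "cerebrum-M",
    "cerebellum-F",
    "cerebellum-M",
    "heart-F",
    "heart-M",
    "kidney-F",
    "kidney-M",
    "liver-F",
    "liver-M",
    "testis",
)

#: Nine vertebrate species with multi-tissue expression data: eight mammals
#: plus chicken as the non-mammalian reference.
DEFAULT_SPECIES: tuple[str, ...] = (
    "human",
    "chimpanzee",
    "gorilla",
    "orangutan",
    "macaque",
    "mouse",
    "opossum",
    "platypus",
    "chicken",
)

#: Ultrametric default species tree; branch lengths are in units of K_s/2 so
#: that leaf-to-leaf path lengths equal pairwise median K_s (human-chimpanzee
#: 0.01 up to human-chicken 1.66, with human-platypus at 1.41).
DEFAULT_SPECIES_TREE: str = (
    "((((((((human:0.005,chimpanzee:0.005)hominini:0.005,gorilla:0.01)"
    "homininae:0.01,orangutan:0.02)hominidae:0.015,macaque:0.035)"
    "catarrhini:0.19,mouse:0.225)boreoeutheria:0.275,opossum:0.5)"
    "theria:0.205,platypus:0.705)mammalia:0.125,chicken:0.83)amniota;"
)

CLASS_LABELS: tuple[str, ...] = (
    "CONSERVED",
    "NEOFUNC_PARENT",
    "NEOFUNC_CHILD",
    "SUBFUNC",
    "SPECIALIZED",
)


@dataclass
class PipelineConfig:
    """Settings that control a full pipeline run.

    Parameters
    ----------
    expression_threshold : float
        A gene is "expressed" if its value is >= this threshold (FPKM-like
        units) in at least one tissue. Default 1.0.
    siqr_multiplier : float
        Divergence cutoff is ``median + siqr_multiplier * SIQR`` of the
        single-copy baseline distances. Default 1.0.
    quantile_method : str
        Quantile convention for Q1/Q3 (any method accepted by
        :func:`numpy.quantile`). Default ``"linear"``.
    per_species_normalization : bool
        If True, quantile-normalize each species' matrix separately instead
        of pooling all samples of all species into one normalization set.
    species_priority : tuple of str
        Deterministic tie-break order for outgroup-species selection.
    tissue_order : tuple of str
        Canonical tissue ordering; also the argmax tie-break order.
    require_full_coverage : bool
        If True, parsimony dating demands a copy number for every leaf of
        the species tree; if False (default) missing species are treated as
        uninformative.
    seed : int
        Seed recorded in the manifest and used by any stochastic stage.
    """

    expression_threshold: float = 1.0
    siqr_multiplier: float = 1.0
    quantile_method: str = "linear"
    per_species_normalization: bool = False
    species_priority: tuple[str, ...] = DEFAULT_SPECIES
    tissue_order: tuple[str, ...] = CANONICAL_TISSUES
    require_full_coverage: bool = False
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("species_priority", "tissue_order"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
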