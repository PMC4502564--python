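"""Ground-truth-labeled synthetic expression datasets.

The generator emulates the statistical structure the classification method
assumes, so every pipeline stage is testable without external RNA-seq data:

* Ancestral relative profiles are Dirichlet draws (concentration < 1 gives
  the tissue-biased profiles typical of multi-tissue expression); absolute
  rows scale them by a log-normally distributed total expression.
* Single-copy genes drift between species via per-tissue multiplicative
  log-normal noise whose spread grows with the species pair's K_s, so
  baseline divergence E_S1,S2 increases with evolutionary distance.
* Trios plant the five retention classes geometrically: conserved copies
  stay at the ancestral profile; neofunctionalized copies are re-drawn from
  a spiky Dirichlet (one novel tissue-specific profile); subfunctionalized
  copies partition the ancestral tissues so their sum reconstructs the
  ancestral row exactly; specialized copies get two novel profiles with
  distinct top tissues.

Everything is driven by a single :class:`numpy.random.Generator`, so a fixed
seed reproduces the full bundle bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CANONICAL_TISSUES, CLASS_LABELS, DEFAULT_SPECIES_TREE
from .phylogeny import SpeciesTree, select_outgroup_species

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SimulatedBundle",
    "simulate_ancestral_profile",
    "simulate_single_copy_pair",
    "simulate_trio",
    "simulate_dataset",
    "simulate_divergence_series",
]

DIVERGED_CLASSES = tuple(l for l in CLASS_LABELS if l != "CONSERVED")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-data generator.

    noise_sd is the log-normal sd of per-tissue multiplicative measurement
    noise applied to every observed expression row; drift_per_ks scales the
    additional evolutionary divergence with the species pair's K_s.
    """

    seed: int = 0
    n_tissues: int = 11
    tissue_labels: tuple[str, ...] = CANONICAL_TISSUES
    n_single_copy: int = 300
    n_trios_per_class: int = 200
    noise_sd: float = 0.1
    drift_per_ks: float = 0.1
    ancestral_concentration: float = 0.5
    neo_concentration: float = 0.1
    expression_scale: float = 100.0
    expression_log_sd: float = 1.0
    species_tree: str = DEFAULT_SPECIES_TREE
    ks_per_pair: dict | None = None
    #: optional per-tissue weights biasing which tissue a neofunctionalized
    #: profile peaks in (planted enrichment direction); None = unbiased
    neo_top_tissue_weights: tuple[float, ...] | None = None
    #: extra copy-number families that single-gain parsimony cannot resolve
    n_unresolved_families: int = 5
    #: tissues absent from particular species' panels, e.g. {"platypus": ["testis"]}
    missing_tissues: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_tissues != len(self.tissue_labels):
            self.tissue_labels = tuple(self.tissue_labels[: self.n_tissues])
            if len(self.tissue_labels) != self.n_tissues:
                raise ValueError("n_tissues exceeds available tissue labels")
        for name in ("noise_sd", "drift_per_ks", "ancestral_concentration",
                     "neo_concentration", "expression_scale", "expression_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    pair_id: str
    planted_class: str
    planted_origin_branch: str
    planted_parent: str


@dataclass
class SimulatedBundle:
    """A complete, internally consistent input bundle for the pipeline."""

    matrices: dict  # species -> ExpressionMatrix
    orthologs: dict  # (species, species) -> DataFrame(gene_1, gene_2)
    trios: pd.DataFrame
    copy_number: pd.DataFrame
    alignment_flags: pd.DataFrame
    ks_table: pd.DataFrame
    ground_truth: pd.DataFrame
    tree_newick: str
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        (outdir / "expression").mkdir(parents=True, exist_ok=True)
        (outdir / "orthologs").mkdir(parents=True, exist_ok=True)
        (outdir / "species_tree.nwk").write_text(self.tree_newick + "\n")
        for species, matrix in self.matrices.items():
            matrix.to_tsv(outdir / "expression" / f"{species}.tsv")
        for (sp1, sp2), table in self.orthologs.items():
            table.to_csv(outdir / "orthologs" / f"{sp1}__{sp2}.tsv", sep="\t", index=False)
        self.trios.to_csv(outdir / "trios.tsv", sep="\t", index=False)
        self.copy_number.to_csv(outdir / "copy_number.tsv", sep="\t", index=False)
        self.alignment_flags.to_csv(outdir / "alignment_flags.tsv", sep="\t", index=False)
        self.ks_table.to_csv(outdir / "ks.tsv", sep="\t", index=False)
        self.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        snapshot = dataclasses.asdict(self.config)
        (outdir / "generator_config.json").write_text(json.dumps(snapshot, indent=2, default=list) + "\n")
        return outdir


def _noisy(row: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Per-tissue multiplicative log-normal noise (sd = 0 leaves the row exact)."""
    return row * rng.lognormal(0.0, sd, size=row.size)


def simulate_ancestral_profile(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Absolute expression row of an ancestral gene.

    The relative profile is Dirichlet(ancestral_concentration); the total
    expression is log-normal around expression_scale.
    """
    rel = rng.dirichlet(np.full(config.n_tissues, config.ancestral_concentration))
    total = rng.lognormal(math.log(config.expression_scale), config.expression_log_sd)
    return rel * total


def simulate_single_copy_pair(
    ancestral_row: np.ndarray,
    ks: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed rows of a single-copy ortholog in two sister species.

    Each species' row perturbs the ancestral row with log-normal noise of
    sd = noise_sd + drift_per_ks * ks, so expected divergence grows with
    evolutionary distance.
    """
    if ks < 0:
        raise ValueError("ks must be >= 0")
    sd = config.noise_sd + config.drift_per_ks * ks
    return _noisy(ancestral_row, sd, rng), _noisy(ancestral_row, sd, rng)


def _spiky_profile(
    config: GeneratorConfig,
    rng: np.random.Generator,
    forbid_top: int | None = None,
) -> np.ndarray:
    """A novel tissue-specific relative profile (Dirichlet, concentration << 1).

    If neo_top_tissue_weights is set, the profile's peak tissue is drawn
    from those weights (planted enrichment direction); optionally a given
    top tissue is forbidden (used to keep specialized copies distinct).
    """
    for _ in range(1000):
        rel = rng.dirichlet(np.full(config.n_tissues, config.neo_concentration))
        if config.neo_top_tissue_weights is not None:
            weights = np.asarray(config.neo_top_tissue_weights, dtype=float)
            weights = weights / weights.sum()
            target = int(rng.choice(config.n_tissues, p=weights))
            current = int(np.argmax(rel))
            rel[[current, target]] = rel[[target, current]]
        if forbid_top is None or int(np.argmax(rel)) != forbid_top:
            return rel
    raise RuntimeError("failed to draw a distinct tissue-specific profile")


def simulate_trio(
    planted_class: str,
    ancestral_row: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    ks: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed (parent, child, outgroup) rows with a planted retention class.

    The outgroup row is the ancestral row plus noise. Class geometry before
    noise: CONSERVED keeps both copies at the ancestral row; NEOFUNC_* gives
    the diverged copy a novel spiky profile; SUBFUNC partitions the expressed
    tissues between the copies so parent + child = ancestral exactly;
    SPECIALIZED gives both copies novel profiles with distinct top tissues.
    All rows then receive log-normal noise of sd = noise_sd + drift_per_ks*ks.
    """
    if planted_class not in CLASS_LABELS:
        raise ValueError(f"unknown class {planted_class!r}")
    anc = np.asarray(ancestral_row, dtype=float)
    sd = config.noise_sd + config.drift_per_ks * ks
    total = anc.sum()
    if total <= 0:
        raise ValueError("ancestral row has zero total expression")

    if planted_class == "CONSERVED":
        parent_signal, child_signal = anc, anc
    elif planted_class == "NEOFUNC_PARENT":
        parent_signal, child_signal = _spiky_profile(config, rng) * total, anc
    elif planted_class == "NEOFUNC_CHILD":
        parent_signal, child_signal = anc, _spiky_profile(config, rng) * total
    elif planted_class == "SUBFUNC":
        expressed = np.flatnonzero(anc > 0)
        if expressed.size < 2:
            raise ValueError("ancestral profile with < 2 expressed tissues cannot be subfunctionalized")
        while True:  # exchangeable half split; reject empty sides
            mask = np.zeros(anc.size, dtype=bool)
            mask[expressed] = rng.random(expressed.size) < 0.5
            if mask.any() and not mask[expressed].all():
                break
        parent_signal = np.where(mask, anc, 0.0)
        child_signal = anc - parent_signal  # sums to ancestral exactly
    else:  # SPECIALIZED
        parent_rel = _spiky_profile(config, rng)
        child_rel = _spiky_profile(config, rng, forbid_top=int(np.argmax(parent_rel)))
        parent_signal = parent_rel * total / 2.0
        child_signal = child_rel * total / 2.0

    return (
        _noisy(parent_signal, sd, rng),
        _noisy(child_signal, sd, rng),
        _noisy(anc, sd, rng),
    )


def _brownian_leaf_signals(
    anc: np.ndarray,
    tree: SpeciesTree,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-species evolved signal rows: log-space Brownian drift along the
    tree with per-unit-K_s variance drift_per_ks**2, applied to the ancestral
    row. drift_per_ks = 0 leaves every species at the ancestral row exactly."""
    if config.drift_per_ks == 0:
        return {leaf: anc for leaf in tree.leaf_names}
    signals: dict[str, np.ndarray] = {}
    shifts = {id(tree.tree.seed_node): np.zeros(anc.size)}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        step = rng.normal(0.0, config.drift_per_ks * math.sqrt(length), size=anc.size)
        shifts[id(node)] = shifts[id(node.parent_node)] + step
        if node.is_leaf():
            signals[node.taxon.label] = anc * np.exp(shifts[id(node)])
    return signals


def _class_signals(
    planted_class: str,
    focal_signal: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Parent/child signal rows in the focal species for a planted class."""
    total = focal_signal.sum()
    if planted_class == "CONSERVED":
        return focal_signal, focal_signal
    if planted_class == "NEOFUNC_PARENT":
        return _spiky_profile(config, rng) * total, focal_signal
    if planted_class == "NEOFUNC_CHILD":
        return focal_signal, _spiky_profile(config, rng) * total
    if planted_class == "SUBFUNC":
        expressed = np.flatnonzero(focal_signal > 0)
        if expressed.size < 2:
            raise ValueError("cannot subfunctionalize a single-tissue profile")
        while True:
            mask = np.zeros(focal_signal.size, dtype=bool)
            mask[expressed] = rng.random(expressed.size) < 0.5
            if mask.any() and not mask[expressed].all():
                break
        parent = np.where(mask, focal_signal, 0.0)
        return parent, focal_signal - parent
    parent_rel = _spiky_profile(config, rng)
    child_rel = _spiky_profile(config, rng, forbid_top=int(np.argmax(parent_rel)))
    return parent_rel * total / 2.0, child_rel * total / 2.0


def simulate_dataset(
    config: GeneratorConfig, outdir: str | Path | None = None
) -> SimulatedBundle:
    """Generate a complete input bundle for the full pipeline.

    Single-copy families are present in every species and populate the
    ortholog tables of all species pairs. Each duplicate trio plants one
    retention class in a focal species (duplication on the focal terminal
    branch, so the copy-number pattern is resolvable by single-gain
    parsimony), with the outgroup gene in the nearest species on the tree;
    alignment flags mark the planted parent. A few additional families carry
    non-clade copy-number patterns and ambiguous flags to exercise the
    exclusion paths.
    """
    from .expression import ExpressionMatrix  # local import to avoid cycle

    rng = np.random.default_rng(config.seed)
    tree = SpeciesTree(config.species_tree)
    species = list(tree.leaf_names)
    if len(species) < 2:
        raise ValueError("species tree must have at least two leaves")

    ks_per_pair: dict[tuple[str, str], float] = {}
    for i, sp1 in enumerate(species):
        for sp2 in species[i + 1 :]:
            key = tuple(sorted((sp1, sp2)))
            if config.ks_per_pair is not None:
                lookup = {tuple(sorted(k)) if isinstance(k, (tuple, list)) else tuple(sorted(k.split("|"))): v
                          for k, v in config.ks_per_pair.items()}
                if key not in lookup:
                    raise ValueError(f"ks_per_pair missing species pair {key}")
                ks_per_pair[key] = float(lookup[key])
            else:
                ks_per_pair[key] = round(tree.leaf_distance(sp1, sp2), 10)

    tissues = {
        sp: [t for t in config.tissue_labels if t not in set(config.missing_tissues.get(sp, ()))]
        for sp in species
    }

    rows: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in species}

    # --- single-copy ortholog families, present in all species ---
    for fam_idx in range(config.n_single_copy):
        fam = f"SC{fam_idx:05d}"
        anc = simulate_ancestral_profile(config, rng)
        signals = _brownian_leaf_signals(anc, tree, config, rng)
        for sp in species:
            observed = _noisy(signals[sp], config.noise_sd, rng)
            keep = [config.tissue_labels.index(t) for t in tissues[sp]]
            rows[sp][f"{fam}_{sp}"] = observed[keep]

    orthologs = {
        key: pd.DataFrame(
            {
                "gene_1": [f"SC{i:05d}_{key[0]}" for i in range(config.n_single_copy)],
                "gene_2": [f"SC{i:05d}_{key[1]}" for i in range(config.n_single_copy)],
            }
        )
        for key in ks_per_pair
    }

    # --- duplicate trios with planted classes ---
    trio_rows, truth_rows, cn_rows, flag_rows = [], [], [], []
    trio_idx = 0
    for planted_class in CLASS_LABELS:
        for _ in range(config.n_trios_per_class):
            fam = f"DUP{trio_idx:05d}"
            pair_id = f"T{trio_idx:05d}"
            focal = species[trio_idx % len(species)]
            outgroup_sp = select_outgroup_species(tree, focal, [s for s in species if s != focal])
            anc = simulate_ancestral_profile(config, rng)
            signals = _brownian_leaf_signals(anc, tree, config, rng)
            parent_signal, child_signal = _class_signals(
                planted_class, signals[focal], config, rng
            )
            parent_id, child_id = f"{fam}_{focal}_a", f"{fam}_{focal}_b"
            outgroup_id = f"{fam}_{outgroup_sp}"
            keep_focal = [config.tissue_labels.index(t) for t in tissues[focal]]
            keep_out = [config.tissue_labels.index(t) for t in tissues[outgroup_sp]]
            rows[focal][parent_id] = _noisy(parent_signal, config.noise_sd, rng)[keep_focal]
            rows[focal][child_id] = _noisy(child_signal, config.noise_sd, rng)[keep_focal]
            rows[outgroup_sp][outgroup_id] = _noisy(signals[outgroup_sp], config.noise_sd, rng)[keep_out]

            trio_rows.append(
                {
                    "pair_id": pair_id,
                    "focal_species": focal,
                    "parent_gene": parent_id,
                    "child_gene": child_id,
                    "outgroup_species": outgroup_sp,
                    "outgroup_gene": outgroup_id,
                }
            )
            truth_rows.append(
                dataclasses.asdict(
                    GroundTruth(pair_id, planted_class, focal, parent_id)
                )
            )
            for sp in species:
                cn_rows.append(
                    {"family_id": fam, "species": sp, "copy_number": 2 if sp == focal else 1}
                )
            flag_rows.append({"family_id": fam, "copy_id": parent_id, "aligns_to_outgroup": 1})
            flag_rows.append({"family_id": fam, "copy_id": child_id, "aligns_to_outgroup": 0})
            trio_idx += 1

    # --- families single-gain parsimony cannot resolve (exclusion paths) ---
    for k in range(config.n_unresolved_families):
        fam = f"UNR{k:05d}"
        if len(species) >= 3:
            # two copies in two species that are not sisters on the default tree
            carriers = (species[0], species[-1])
        else:
            carriers = tuple(species)  # duplicated in all species
        for sp in species:
            cn_rows.append(
                {"family_id": fam, "species": sp, "copy_number": 2 if sp in carriers else 1}
            )
        flag_rows.append({"family_id": fam, "copy_id": f"{fam}_a", "aligns_to_outgroup": 1})
        flag_rows.append({"family_id": fam, "copy_id": f"{fam}_b", "aligns_to_outgroup": 1})

    matrices = {
        sp: ExpressionMatrix(
            species=sp,
            data=pd.DataFrame.from_dict(rows[sp], orient="index", columns=tissues[sp]),
        )
        for sp in species
    }

    ks_table = pd.DataFrame(
        [
            {
                "species_1": key[0],
                "species_2": key[1],
                "ks_median": ks,
                "ka_median": round(0.15 * ks, 10),
            }
            for key, ks in sorted(ks_per_pair.items())
        ]
    )

    bundle = SimulatedBundle(
        matrices=matrices,
        orthologs=orthologs,
        trios=pd.DataFrame(trio_rows),
        copy_number=pd.DataFrame(cn_rows),
        alignment_flags=pd.DataFrame(flag_rows),
        ks_table=ks_table,
        ground_truth=pd.DataFrame(truth_rows),
        tree_newick=config.species_tree.strip(),
        config=config,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def simulate_divergence_series(
    config: GeneratorConfig,
    ks_values: Sequence[float],
    n_pairs_per_ks: int = 300,
    n_trios_per_ks: int = 300,
    event_rate_per_ks: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Proportion of conserved duplicates (and single-copy genes) vs K_s.

    For each K_s level: single-copy pairs set the baseline distribution and
    its median+SIQR cutoff; trios are planted conserved with probability
    exp(-event_rate_per_ks * K_s), otherwise uniformly one of the four
    diverged classes — class events accumulate with evolutionary distance.
    Returns one row per K_s with observed conserved proportions.
    """
    from .classification import DuplicateClassifier, euclidean_distance
    from .expression import combine_profiles, relative_profile

    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = tuple(config.tissue_labels)
    out = []
    for ks in ks_values:
        distances = np.empty(n_pairs_per_ks)
        for i in range(n_pairs_per_ks):
            anc = simulate_ancestral_profile(config, rng)
            row1, row2 = simulate_single_copy_pair(anc, ks, config, rng)
            distances[i] = euclidean_distance(
                relative_profile(row1, labels), relative_profile(row2, labels)
            )
        clf = DuplicateClassifier().fit(distances)

        n_conserved_planted = 0
        triples = np.empty((n_trios_per_ks, 3))
        planted_conserved = np.empty(n_trios_per_ks, dtype=bool)
        for i in range(n_trios_per_ks):
            if rng.random() < math.exp(-event_rate_per_ks * ks):
                planted = "CONSERVED"
            else:
                planted = DIVERGED_CLASSES[int(rng.integers(len(DIVERGED_CLASSES)))]
            planted_conserved[i] = planted == "CONSERVED"
            anc = simulate_ancestral_profile(config, rng)
            parent, child, outgroup = simulate_trio(planted, anc, config, rng, ks=ks)
            o = relative_profile(outgroup, labels)
            triples[i] = (
                euclidean_distance(relative_profile(parent, labels), o),
                euclidean_distance(relative_profile(child, labels), o),
                euclidean_distance(combine_profiles(parent, child, labels), o),
            )
        predicted = clf.predict(triples)
        out.append(
            {
                "ks": float(ks),
                "cutoff": clf.cutoff_,
                "n_trios": n_trios_per_ks,
                "planted_conserved": int(planted_conserved.sum()),
                "proportion_conserved": float(np.mean(predicted == "CONSERVED")),
                "proportion_conserved_single_copy": float(
                    np.mean(distances <= clf.cutoff_)
                ),
            }
        )
    return pd.DataFrame(out)
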