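"""Reading and validating the TSV/Newick input bundle.

Bundle layout (all plain text, gzip-transparent for expression matrices):

    species_tree.nwk            rooted Newick species tree
    expression/<species>.tsv    gene_id + tissue columns, FPKM-like values
    orthologs/<sp1>__<sp2>.tsv  single-copy ortholog pairs (gene_1, gene_2)
    trios.tsv                   pair_id, focal_species, parent_gene,
                                child_gene, outgroup_species, outgroup_gene
    copy_number.tsv             family_id, species, copy_number
    alignment_flags.tsv         family_id, copy_id, aligns_to_outgroup
    ks.tsv                      species_1, species_2, ks_median[, ka_median]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import CANONICAL_TISSUES
from .expression import ExpressionMatrix
from .phylogeny import SpeciesTree

__all__ = ["Bundle", "ValidationReport", "load_bundle", "validate_inputs"]

TRIO_COLUMNS = (
    "pair_id",
    "focal_species",
    "parent_gene",
    "child_gene",
    "outgroup_species",
    "outgroup_gene",
)


@dataclass
class Bundle:
    tree: SpeciesTree
    tree_newick: str
    matrices: dict
    orthologs: dict
    trios: pd.DataFrame
    copy_number: pd.DataFrame | None
    alignment_flags: pd.DataFrame | None
    ks_per_pair: dict
    ka_per_pair: dict


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _read_tsv(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    return frame


def load_bundle(indir: str | Path) -> Bundle:
    """Load a pipeline input bundle from a directory."""
    indir = Path(indir)
    tree_path = indir / "species_tree.nwk"
    if not tree_path.exists():
        raise FileNotFoundError(f"missing input: {tree_path}")
    newick = tree_path.read_text().strip()
    tree = SpeciesTree(newick)

    matrices = {}
    expr_dir = indir / "expression"
    if not expr_dir.is_dir():
        raise FileNotFoundError(f"missing input: {expr_dir}")
    for path in sorted(expr_dir.glob("*.tsv*")):
        species = path.name.split(".")[0]
        matrices[species] = ExpressionMatrix.from_tsv(path, species=species)
    if not matrices:
        raise FileNotFoundError(f"no expression matrices in {expr_dir}")

    orthologs = {}
    orth_dir = indir / "orthologs"
    if orth_dir.is_dir():
        for path in sorted(orth_dir.glob("*.tsv*")):
            stem = path.name.split(".")[0]
            sp1, _, sp2 = stem.partition("__")
            key = tuple(sorted((sp1, sp2)))
            table = _read_tsv(path, ("gene_1", "gene_2"))
            if key != (sp1, sp2):  # keep gene_1 aligned with the sorted key
                table = table.rename(columns={"gene_1": "gene_2", "gene_2": "gene_1"})
            orthologs[key] = table[["gene_1", "gene_2"]]

    trios_path = indir / "trios.tsv"
    if not trios_path.exists():
        raise FileNotFoundError(f"missing input: {trios_path}")
    trios = _read_tsv(trios_path, TRIO_COLUMNS)

    copy_number = None
    if (indir / "copy_number.tsv").exists():
        copy_number = _read_tsv(indir / "copy_number.tsv", ("family_id", "species", "copy_number"))
    alignment_flags = None
    if (indir / "alignment_flags.tsv").exists():
        alignment_flags = _read_tsv(
            indir / "alignment_flags.tsv", ("family_id", "copy_id", "aligns_to_outgroup")
        )

    ks_per_pair: dict = {}
    ka_per_pair: dict = {}
    ks_path = indir / "ks.tsv"
    if ks_path.exists():
        ks_table = _read_tsv(ks_path, ("species_1", "species_2", "ks_median"))
        for row in ks_table.itertuples(index=False):
            key = tuple(sorted((row.species_1, row.species_2)))
            ks_per_pair[key] = float(row.ks_median)
            if hasattr(row, "ka_median") and pd.notna(row.ka_median):
                ka_per_pair[key] = float(row.ka_median)

    return Bundle(
        tree=tree,
        tree_newick=newick,
        matrices=matrices,
        orthologs=orthologs,
        trios=trios,
        copy_number=copy_number,
        alignment_flags=alignment_flags,
        ks_per_pair=ks_per_pair,
        ka_per_pair=ka_per_pair,
    )


def validate_inputs(indir: str | Path) -> ValidationReport:
    """Schema and cross-reference checks on an input bundle.

    Fatal errors: unreadable/missing files, unknown tissue labels, species
    absent from the tree, trio genes absent from their species' matrix.
    Non-fatal warnings: missing optional tables, tissue panels narrower
    than the canonical vocabulary.
    """
    report = ValidationReport()
    try:
        bundle = load_bundle(indir)
    except (FileNotFoundError, ValueError) as exc:
        report.errors.append(str(exc))
        return report

    leaf_set = set(bundle.tree.leaf_names)
    for species, matrix in bundle.matrices.items():
        if species not in leaf_set:
            report.errors.append(f"species {species!r} not a leaf of the species tree")
        unknown = [t for t in matrix.tissue_labels if t not in CANONICAL_TISSUES]
        if unknown:  # unreachable via ExpressionMatrix, kept for raw frames
            report.errors.append(f"unknown tissue label(s) {unknown} in {species}")
        if len(matrix.tissue_labels) < len(CANONICAL_TISSUES):
            report.warnings.append(
                f"{species}: {len(matrix.tissue_labels)}/{len(CANONICAL_TISSUES)} canonical tissues"
            )

    for trio in bundle.trios.itertuples(index=False):
        for species_attr, gene_attr in (
            ("focal_species", "parent_gene"),
            ("focal_species", "child_gene"),
            ("outgroup_species", "outgroup_gene"),
        ):
            species = getattr(trio, species_attr)
            gene = getattr(trio, gene_attr)
            if species not in bundle.matrices:
                report.errors.append(f"trio {trio.pair_id}: no expression matrix for {species!r}")
            elif gene not in bundle.matrices[species].data.index:
                report.errors.append(
                    f"trio {trio.pair_id}: gene {gene!r} absent from {species} matrix"
                )
        if trio.focal_species == trio.outgroup_species:
            report.errors.append(f"trio {trio.pair_id}: focal equals outgroup species")
        if trio.parent_gene == trio.child_gene:
            report.errors.append(f"trio {trio.pair_id}: parent equals child gene")

    if not bundle.orthologs:
        report.warnings.append("no ortholog tables found")
    if not bundle.ks_per_pair:
        report.warnings.append("no ks table found")
    if bundle.copy_number is None:
        report.warnings.append("no copy_number table found")
    if bundle.alignment_flags is None:
        report.warnings.append("no alignment_flags table found")
    return report
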