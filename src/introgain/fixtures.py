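"""Packaged machine-readable transcriptions of the published survey tables.

The package ships four small text fixtures: the DNA-transposon and
retroelement gene-family metadata (TE group, origin route, intron
location and count range), the per-gene origin node on the species
tree, the intron-position-conservation states across the four placental
superorders, and the named-node species tree itself.  From these a
three-state (present/absent/unknown) gene presence matrix over the tree
leaves is derived mechanically: origin at node N means presence in
every sampled leaf under N and absence outside it, with "incomplete"
and undetermined conservation cells censored to unknown.
"""

from __future__ import annotations

import io
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .homology import PRESENT, ABSENT, UNKNOWN
from .timing import GainLossScenario, SpeciesTree

__all__ = [
    "load_species_tree",
    "load_family_metadata",
    "load_origin_table",
    "load_conservation_table",
    "build_presence_matrix",
    "fixture_scenarios",
    "package_paper_fixtures",
    "SUPERORDER_LEAVES",
    "ZNF_BASELINES",
]

#: leaf species sampled per placental superorder in the packaged tree
SUPERORDER_LEAVES = {
    "Euarchontoglires": ["human", "mouse"],
    "Laurasiatheria": ["dog", "cow"],
    "Xenarthra": ["sloth", "armadillo"],
    "Afrotheria": ["elephant", "tenrec"],
}

#: ancestral CDS intron counts of placental-specific zinc-finger families,
#: the baseline for the excess-intron screen
ZNF_BASELINES = {
    "SCAN_ZNF": (1, 1),
    "KRAB_ZNF": (1, 2),
    "SCAN_KRAB_ZNF": (2, 3),
}


def _data_text(name: str) -> str:
    return resources.files("introgain.data").joinpath(name).read_text()


def _read_tsv(name: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(_data_text(name)), sep="\t", comment="#",
                       dtype={"intron_min": "Int64", "intron_max": "Int64"})


def load_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(_data_text("species_tree.nwk"), is_path=False)


def load_family_metadata(progenitor_class: Optional[str] = None) -> pd.DataFrame:
    """Gene-family metadata rows (both TE classes unless filtered)."""
    dna = _read_tsv("dna_transposon_families.tsv")
    retro = _read_tsv("retroelement_families.tsv")
    df = pd.concat([dna, retro], ignore_index=True, sort=False)
    df["fusion_exception"] = (
        df["fusion_exception"].astype(str).str.lower() == "true"
    )
    if progenitor_class is not None:
        df = df[df["progenitor_class"] == progenitor_class].reset_index(drop=True)
    return df


def load_origin_table() -> pd.DataFrame:
    return _read_tsv("gene_origins.tsv")


def load_conservation_table() -> pd.DataFrame:
    return _read_tsv("intron_position_conservation.tsv")


def build_presence_matrix(tree: Optional[SpeciesTree] = None) -> pd.DataFrame:
    """Derive the three-state gene presence matrix over the tree leaves.

    A gene with origin node N is present in every leaf under N and
    absent elsewhere; superorders whose conservation cell is
    "incomplete" or "unknown" are censored to unknown for that gene.
    Values are P/A/U strings; rows = gene families, columns = leaves.
    """
    tree = tree or load_species_tree()
    origins = load_origin_table()
    conservation = load_conservation_table().set_index("family_id")
    leaves = tree.leaves()

    code = {PRESENT: "P", ABSENT: "A", UNKNOWN: "U"}
    rows = {}
    for _, rec in origins.iterrows():
        family, node_label = rec["family_id"], rec["origin_node"]
        under = set(tree.leaves_under(tree.node(node_label)))
        states = {lf: (PRESENT if lf in under else ABSENT) for lf in leaves}
        if family in conservation.index:
            for superorder, so_leaves in SUPERORDER_LEAVES.items():
                if conservation.at[family, superorder] in ("incomplete", "unknown"):
                    for lf in so_leaves:
                        states[lf] = UNKNOWN
        rows[family] = {lf: code[states[lf]] for lf in leaves}
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=leaves)
    matrix.index.name = "family_id"
    return matrix


def presence_states(matrix: pd.DataFrame, family_id: str) -> dict[str, str]:
    decode = {"P": PRESENT, "A": ABSENT, "U": UNKNOWN}
    return {sp: decode[str(v)] for sp, v in matrix.loc[family_id].items()}


def fixture_scenarios(tree: Optional[SpeciesTree] = None) -> list[GainLossScenario]:
    """Gain/loss scenarios for the placed fixture families.

    Origin nodes are recomputed from the derived presence matrix (not
    copied from the origin table), and each family's intron-count range
    is attached for min/max tallies.
    """
    from .timing import place_gene_origin

    tree = tree or load_species_tree()
    matrix = build_presence_matrix(tree)
    meta = load_family_metadata().set_index("family_id")
    scenarios = []
    for family_id in matrix.index:
        origin = place_gene_origin(tree, presence_states(matrix, family_id))
        count_range = None
        progenitor = None
        if family_id in meta.index:
            rec = meta.loc[family_id]
            progenitor = rec["progenitor_class"]
            if pd.notna(rec["intron_min"]) and pd.notna(rec["intron_max"]):
                count_range = (int(rec["intron_min"]), int(rec["intron_max"]))
        scenarios.append(GainLossScenario(
            family_id=family_id, origin_node=origin,
            count_range=count_range, progenitor_class=progenitor,
        ))
    return scenarios


def package_paper_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the fixture bundle (metadata, presence matrix, tree) to a dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    meta_path = outdir / "family_metadata.tsv"
    with open(meta_path, "w") as fh:
        fh.write("# Domesticated-gene family metadata (published survey "
                 "transcription).\n")
        load_family_metadata().to_csv(fh, sep="\t", index=False)
    paths["family_metadata"] = meta_path

    tree = load_species_tree()
    tree_path = outdir / "species_tree.nwk"
    tree_path.write_text(_data_text("species_tree.nwk"))
    paths["species_tree"] = tree_path

    matrix = build_presence_matrix(tree)
    matrix_path = outdir / "gene_presence_matrix.tsv"
    with open(matrix_path, "w") as fh:
        fh.write(
            "# Three-state gene presence matrix (P/A/U) over the packaged tree "
            "leaves,\n"
            "# derived mechanically from the transcribed origin table: origin "
            "at node N\n"
            "# => present in every sampled leaf under N, absent outside; "
            "superorders with\n"
            "# incomplete/undetermined conservation cells are censored to "
            "unknown.\n"
        )
        matrix.to_csv(fh, sep="\t")
    paths["presence_matrix"] = matrix_path

    origins_path = outdir / "gene_origins.tsv"
    origins_path.write_text(_data_text("gene_origins.tsv"))
    paths["gene_origins"] = origins_path

    conservation_path = outdir / "intron_position_conservation.tsv"
    conservation_path.write_text(_data_text("intron_position_conservation.tsv"))
    paths["conservation"] = conservation_path
    return paths
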