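"""Dollo-style placement of gene origins and intron gains on a species tree.

The ancestral state of a domesticated gene is intronless, so each
homologous intron site is gained exactly once; losses are added as
needed.  The gain node for a site is the MRCA of the species carrying
the intron (understood as a gain on the stem branch leading to that
clade), and the minimal loss set is the stems of the maximal all-absent
subtrees beneath it.  Unknown states are uninformative: they never pull
the MRCA and never force a loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy
import pandas as pd

from .homology import IntronSite, PRESENT, ABSENT, UNKNOWN

__all__ = [
    "SpeciesTree",
    "GainLossScenario",
    "EligibilityRecord",
    "filter_eligible",
    "place_gene_origin",
    "place_site_gain",
    "place_sites",
    "tally_gains",
    "flag_excess_introns",
]


class TimingError(ValueError):
    pass


class SpeciesTree:
    """Rooted species tree with named internal nodes (thin dendropy wrapper)."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._by_label: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            label = self.node_label(node)
            if label:
                if label in self._by_label:
                    raise TimingError(f"duplicate node label {label!r}")
                self._by_label[label] = node

    @classmethod
    def from_newick(cls, source: str, is_path: bool = True) -> "SpeciesTree":
        kwargs = dict(schema="newick", suppress_internal_node_taxa=True,
                      preserve_underscores=True)
        if is_path:
            tree = dendropy.Tree.get(path=str(source), **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
        tree.is_rooted = True
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    @staticmethod
    def node_label(node: dendropy.Node) -> Optional[str]:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def leaves(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def node(self, label: str) -> dendropy.Node:
        try:
            return self._by_label[label]
        except KeyError:
            raise TimingError(f"no node labelled {label!r} in tree") from None

    def leaves_under(self, node: dendropy.Node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]

    def mrca(self, leaf_labels: Iterable[str]) -> dendropy.Node:
        labels = list(leaf_labels)
        if not labels:
            raise TimingError("MRCA of an empty leaf set")
        missing = [l for l in labels if l not in self._by_label]
        if missing:
            raise TimingError(f"species not in tree: {missing}")
        if len(labels) == 1:
            return self._by_label[labels[0]]
        return self.tree.mrca(taxa=[self._by_label[l].taxon for l in labels])

    def is_ancestor_or_equal(self, anc: dendropy.Node,
                             node: dendropy.Node) -> bool:
        cur: Optional[dendropy.Node] = node
        while cur is not None:
            if cur is anc:
                return True
            cur = cur.parent_node
        return False


@dataclass
class GainLossScenario:
    """Per-family origin node, per-site gain placements, and loss branches."""

    family_id: str
    origin_node: str
    site_gains: dict[str, str] = field(default_factory=dict)
    site_losses: dict[str, set[str]] = field(default_factory=dict)
    # (min, max) intron count carried from literature-style fixtures when
    # per-site placements are unavailable; attributed to the origin node
    count_range: Optional[tuple[int, int]] = None
    progenitor_class: Optional[str] = None

    @property
    def per_node_gain_count(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for node in self.site_gains.values():
            counts[node] = counts.get(node, 0) + 1
        return counts


@dataclass
class EligibilityRecord:
    family_id: str
    origin_route: str
    eligible: bool
    reason: str


def filter_eligible(groups) -> list[EligibilityRecord]:
    """Eligibility of families for intron gain timing.

    Only whole-TE domestications have an unambiguous intronless ancestral
    structure.  Genes built by 3'-exon fusion or by DNA-binding-domain
    exon shuffling carry pre-existing host exons and are excluded, as are
    retroelement families flagged as fusion exceptions (SCAND3-style).
    Accepts any records with ``family_id``, ``origin_route``,
    ``progenitor_class`` and optionally ``fusion_exception`` attributes.
    """
    records = []
    for g in groups:
        route = getattr(g, "origin_route", None)
        if not route:
            raise TimingError(f"family {g.family_id}: missing origin_route")
        if getattr(g, "fusion_exception", False):
            rec = EligibilityRecord(
                g.family_id, route, False,
                "flagged fusion exception: host-gene fusion obscures the "
                "ancestral intronless structure",
            )
        elif route == "whole_TE":
            rec = EligibilityRecord(
                g.family_id, route, True, "whole-TE domestication"
            )
        elif route in ("fusion_3prime", "DBD_shuffle"):
            rec = EligibilityRecord(
                g.family_id, route, False,
                f"{route}: fused transposase/DBD exons excluded from intron "
                f"gain inference",
            )
        elif getattr(g, "progenitor_class", None) == "retroelement":
            rec = EligibilityRecord(g.family_id, route, True,
                                    "retroelement, no fusion")
        else:
            raise TimingError(
                f"family {g.family_id}: unrecognized origin_route {route!r}"
            )
        records.append(rec)
    return records


def place_gene_origin(tree: SpeciesTree,
                      gene_presence: dict[str, str]) -> str:
    """MRCA of species in which the gene is present.

    Unknown states are uninformative.  Returns the clade name of the
    origin node (the gain is on the stem branch leading to it); a gene
    present in a single species reports that leaf.
    """
    present = [sp for sp, st in gene_presence.items() if st == PRESENT]
    if not present:
        raise TimingError("gene present in no species")
    node = tree.mrca(present)
    label = tree.node_label(node)
    if label is None:
        raise TimingError("origin node has no label")
    return label


def place_site_gain(tree: SpeciesTree, origin_node: str,
                    site: IntronSite) -> tuple[str, set[str]]:
    """Single-gain Dollo placement of one intron site.

    Returns (gain node label, loss branch labels).  The gain node is the
    MRCA of the present species; losses are the stem branches (identified
    by child node label) of the maximal subtrees under the gain node
    whose informative leaves are all absent.  Unknown leaves never force
    a loss.
    """
    origin = tree.node(origin_node)
    present = sorted(sp for sp, st in site.states.items() if st == PRESENT)
    if not present:
        raise TimingError(f"site {site.site_id}: no present species")
    under_origin = set(tree.leaves_under(origin))
    outside = [sp for sp in present if sp not in under_origin]
    if outside:
        raise TimingError(
            f"site {site.site_id}: present species {outside} outside the "
            f"origin clade {origin_node} (orthology conflict)"
        )
    gain = tree.mrca(present)
    losses = _minimal_losses(tree, gain, site.states)
    label = tree.node_label(gain)
    return label, losses


def _minimal_losses(tree: SpeciesTree, gain: dendropy.Node,
                    states: dict[str, str]) -> set[str]:
    """Stems of maximal all-absent subtrees under ``gain``."""

    losses: set[str] = set()

    def status(node: dendropy.Node) -> str:
        """'absent' if all informative leaves absent (and >=1), 'none' if no
        informative leaves, else 'mixed' (losses recorded greedily)."""
        if node.is_leaf():
            st = states.get(node.taxon.label, UNKNOWN)
            if st == PRESENT:
                return "mixed"
            return "absent" if st == ABSENT else "none"
        child_status = [(c, status(c)) for c in node.child_nodes()]
        vals = {s for _, s in child_status}
        if vals <= {"absent", "none"}:
            return "absent" if "absent" in vals else "none"
        # some descendant is present: absent children become loss branches
        for child, s in child_status:
            if s == "absent":
                losses.add(_branch_label(tree, child))
        return "mixed"

    top = status(gain)
    if top == "absent":  # cannot happen when gain is MRCA of present leaves
        losses.add(_branch_label(tree, gain))
    return losses


def _branch_label(tree: SpeciesTree, child: dendropy.Node) -> str:
    label = tree.node_label(child)
    if label:
        return label
    # unlabelled internal node: identify the branch by its leaf set
    return "+".join(sorted(tree.leaves_under(child)))


def place_sites(tree: SpeciesTree, family_id: str, origin_node: str,
                sites: list[IntronSite],
                progenitor_class: Optional[str] = None) -> GainLossScenario:
    """Convenience: place every site of a family into one scenario."""
    scenario = GainLossScenario(family_id=family_id, origin_node=origin_node,
                                progenitor_class=progenitor_class)
    for site in sites:
        gain, losses = place_site_gain(tree, origin_node, site)
        scenario.site_gains[site.site_id] = gain
        scenario.site_losses[site.site_id] = losses
    return scenario


def tally_gains(scenarios: list[GainLossScenario],
                tree: SpeciesTree) -> pd.DataFrame:
    """Per-node table of originating families and min/max intron gains.

    Site-resolved scenarios contribute one gain per site at its placed
    node; fixture-style scenarios with a (min, max) count range
    contribute that range at the family's origin node.
    """
    rows: dict[str, dict[str, int]] = {}

    def bucket(node: str) -> dict[str, int]:
        return rows.setdefault(node, {
            "n_families_originating": 0,
            "n_intron_gains_min": 0,
            "n_intron_gains_max": 0,
        })

    for sc in scenarios:
        bucket(sc.origin_node)["n_families_originating"] += 1
        if sc.site_gains:
            for node in sc.site_gains.values():
                b = bucket(node)
                b["n_intron_gains_min"] += 1
                b["n_intron_gains_max"] += 1
        elif sc.count_range is not None:
            lo, hi = sc.count_range
            b = bucket(sc.origin_node)
            b["n_intron_gains_min"] += lo
            b["n_intron_gains_max"] += hi

    if not rows:
        return pd.DataFrame(
            columns=["n_families_originating", "n_intron_gains_min",
                     "n_intron_gains_max"], dtype=int,
        ).rename_axis("node")

    # order nodes root-to-tip as they appear in the tree
    order = []
    for node in tree.tree.preorder_node_iter():
        label = tree.node_label(node)
        if label in rows:
            order.append(label)
    for label in rows:
        if label not in order:
            order.append(label)
    df = pd.DataFrame.from_dict(rows, orient="index").loc[order]
    df.index.name = "node"
    return df


def flag_excess_introns(t, baseline: tuple[int, int],
                        introns=None) -> tuple[bool, int]:
    """Screen a transcript's CDS intron count against a family baseline.

    ``baseline`` is the (min, max) ancestral CDS intron count for the
    gene family (e.g. 1-2 for KRAB-ZNFs); counts above max most probably
    represent newly gained introns.  Returns (flag, excess).
    """
    from .gene_models import extract_introns, REGION_CDS

    lo, hi = baseline
    if lo > hi:
        raise TimingError(f"baseline min {lo} > max {hi}")
    if introns is None:
        introns = extract_introns(t)
    observed = sum(1 for i in introns if i.region_class == REGION_CDS)
    excess = max(0, observed - hi)
    return excess > 0, excess
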