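"""Eligibility filtering and Dollo gain/loss placement on the species tree."""

import itertools

import pandas as pd
import pytest

from introgain.homology import IntronSite
from introgain.timing import (EligibilityRecord, GainLossScenario, SpeciesTree,
                              TimingError, filter_eligible, flag_excess_introns,
                              place_gene_origin, place_site_gain, tally_gains)
from conftest import make_transcript

LEAVES = ["A", "B", "C", "D", "E"]


def make_site(states, phase=None, family="fam1", region="UTR5", column=4):
    return IntronSite(family_id=family, region_class=region, column=column,
                      phase=phase, states=dict(states))


class FakeGroup:
    def __init__(self, family_id, origin_route, progenitor_class="DNA_transposon",
                 fusion_exception=False):
        self.family_id = family_id
        self.origin_route = origin_route
        self.progenitor_class = progenitor_class
        self.fusion_exception = fusion_exception


class TestEligibility:
    def test_whole_te_eligible(self):
        (rec,) = filter_eligible([FakeGroup("POGK", "whole_TE")])
        assert rec.eligible

    def test_dbd_shuffle_excluded_citing_fusion(self):
        (rec,) = filter_eligible([FakeGroup("RAG1", "DBD_shuffle")])
        assert not rec.eligible and "DBD" in rec.reason or "fusion" in rec.reason

    def test_retroelement_default_eligible_scand3_exception(self):
        groups = [
            FakeGroup("PNMA2", "whole_TE", "retroelement"),
            FakeGroup("SCAND3", "whole_TE", "retroelement",
                      fusion_exception=True),
        ]
        recs = filter_eligible(groups)
        assert recs[0].eligible and not recs[1].eligible

    def test_missing_route_raises_naming_family(self):
        with pytest.raises(TimingError, match="POGZ"):
            filter_eligible([FakeGroup("POGZ", "")])

    def test_packaged_dna_transposon_metadata_11_of_36(self):
        from introgain.fixtures import load_family_metadata

        meta = load_family_metadata("DNA_transposon")
        recs = filter_eligible(list(meta.itertuples(index=False)))
        assert len(recs) == 36
        assert sum(r.eligible for r in recs) == 11


class TestGeneOrigin:
    def test_single_species_reports_leaf(self, five_leaf_tree):
        node = place_gene_origin(five_leaf_tree, {"A": "present",
                                                  "B": "absent"})
        assert node == "A"

    def test_eutherian_superorder_pattern_places_at_eutheria(self):
        from introgain.fixtures import load_species_tree

        tree = load_species_tree()
        presence = {lf: "absent" for lf in tree.leaves()}
        for sp in ("human", "dog", "sloth", "elephant"):
            presence[sp] = "present"
        assert place_gene_origin(tree, presence) == "Eutheria"

    def test_human_and_zebrafish_place_at_gnathostomata(self):
        # HARBI1-style origin deep in the jawed-vertebrate ancestor
        from introgain.fixtures import load_species_tree

        tree = load_species_tree()
        presence = {lf: "unknown" for lf in tree.leaves()}
        presence["human"] = presence["zebrafish"] = "present"
        assert place_gene_origin(tree, presence) == "Gnathostomata"

    def test_all_absent_raises(self, five_leaf_tree):
        with pytest.raises(TimingError):
            place_gene_origin(five_leaf_tree, {"A": "absent", "B": "unknown"})


# --- independent exhaustive oracle -----------------------------------------

def _tree_edges(tree):
    out = []
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is not None:
            out.append(node)
    return out


def _oracle_single_gain(tree, states):
    """Exhaustive search over (gain node, loss branch subset).

    Returns (gain label, min losses) where the gain node is the most
    recent among loss-count minimizers; None if no present leaf.
    """
    present = {sp for sp, st in states.items() if st == "present"}
    absent = {sp for sp, st in states.items() if st == "absent"}
    if not present:
        return None
    edges = _tree_edges(tree)
    candidates = [n for n in tree.tree.preorder_node_iter()
                  if present <= {lf.taxon.label for lf in n.leaf_iter()}]
    best = None
    for gain in candidates:
        gain_leaves = {lf.taxon.label for lf in gain.leaf_iter()}
        below = [e for e in edges
                 if tree.is_ancestor_or_equal(gain, e) and e is not gain]
        for r in range(len(below) + 1):
            if best is not None and r > best[1]:
                break
            for combo in itertools.combinations(below, r):
                lost = set()
                for e in combo:
                    lost |= {lf.taxon.label for lf in e.leaf_iter()}
                realized_present = gain_leaves - lost
                if (present <= realized_present
                        and not (absent & realized_present)):
                    depth = sum(1 for _ in _ancestors(gain))
                    key = (r, -depth)
                    if best is None or key < (best[1], -best[2]):
                        best = (gain, r, depth)
                    break
    label = tree.node_label(best[0])
    if label is None:
        label = "+".join(sorted(
            lf.taxon.label for lf in best[0].leaf_iter()))
    return label, best[1]


def _ancestors(node):
    while node.parent_node is not None:
        node = node.parent_node
        yield node


class TestSiteGainDollo:
    def test_all_present_gain_at_origin_no_losses(self, five_leaf_tree):
        site = make_site({sp: "present" for sp in LEAVES})
        gain, losses = place_site_gain(five_leaf_tree, "root", site)
        assert gain == "root" and losses == set()

    def test_hand_pattern_two_losses(self, five_leaf_tree):
        site = make_site({"A": "present", "B": "present", "C": "absent",
                          "D": "present", "E": "absent"})
        gain, losses = place_site_gain(five_leaf_tree, "root", site)
        assert gain == "root"
        assert losses == {"C", "E"}

    def test_terminal_only_presence(self, five_leaf_tree):
        site = make_site({"A": "present", "B": "absent", "C": "absent",
                          "D": "absent", "E": "absent"})
        gain, losses = place_site_gain(five_leaf_tree, "root", site)
        assert gain == "A" and losses == set()

    def test_present_outside_origin_clade_raises(self, five_leaf_tree):
        site = make_site({"A": "present", "C": "present"})
        with pytest.raises(TimingError, match="orthology|outside"):
            place_site_gain(five_leaf_tree, "AB", site)

    def test_exhaustive_oracle_all_243_patterns(self, five_leaf_tree):
        """Dollo placement equals exhaustive single-gain enumeration."""
        for pattern in itertools.product(["present", "absent", "unknown"],
                                         repeat=5):
            states = dict(zip(LEAVES, pattern))
            expected = _oracle_single_gain(five_leaf_tree, states)
            site = make_site(states)
            if expected is None:
                with pytest.raises(TimingError):
                    place_site_gain(five_leaf_tree, "root", site)
                continue
            gain, losses = place_site_gain(five_leaf_tree, "root", site)
            assert (gain, len(losses)) == expected, states

    def test_monotonicity_absent_to_present_never_tipward(self, five_leaf_tree):
        for pattern in itertools.product(["present", "absent"], repeat=5):
            if "present" not in pattern:
                continue
            states = dict(zip(LEAVES, pattern))
            site = make_site(states)
            gain, _ = place_site_gain(five_leaf_tree, "root", site)
            gain_node = five_leaf_tree.node(gain)
            for sp in LEAVES:
                if states[sp] != "absent":
                    continue
                flipped = dict(states, **{sp: "present"})
                new_gain, _ = place_site_gain(five_leaf_tree, "root",
                                              make_site(flipped))
                assert five_leaf_tree.is_ancestor_or_equal(
                    five_leaf_tree.node(new_gain), gain_node)


class TestTally:
    def test_empty_input_empty_table(self, five_leaf_tree):
        table = tally_gains([], five_leaf_tree)
        assert table.empty

    def test_fixture_scenarios_20_families_at_eutheria(self):
        from introgain.fixtures import fixture_scenarios, load_species_tree

        tree = load_species_tree()
        table = tally_gains(fixture_scenarios(tree), tree)
        assert table.at["Eutheria", "n_families_originating"] == 20

    def test_count_ranges_propagate_min_max(self, five_leaf_tree):
        scenarios = [
            GainLossScenario("f1", "root", count_range=(2, 6)),
            GainLossScenario("f2", "root", count_range=(1, 1)),
        ]
        table = tally_gains(scenarios, five_leaf_tree)
        assert table.at["root", "n_intron_gains_min"] == 3
        assert table.at["root", "n_intron_gains_max"] == 7

    def test_site_resolved_scenarios_counted_per_gain_node(self, five_leaf_tree):
        sc = GainLossScenario("f1", "root",
                              site_gains={"s1": "AB", "s2": "AB", "s3": "A"})
        table = tally_gains([sc], five_leaf_tree)
        assert table.at["AB", "n_intron_gains_max"] == 2
        assert table.at["A", "n_intron_gains_min"] == 1


class TestExcessIntrons:
    def test_within_baseline_not_flagged(self):
        t = make_transcript([(0, 99), (200, 299), (400, 499)],
                            [(0, 99), (200, 299), (400, 499)])
        flag, excess = flag_excess_introns(t, (1, 2))
        assert not flag and excess == 0

    def test_excess_over_baseline_flagged(self):
        bounds = [(i * 200, i * 200 + 99) for i in range(6)]
        t = make_transcript(bounds, bounds)
        flag, excess = flag_excess_introns(t, (1, 2))
        assert flag and excess == 3

    def test_inverted_baseline_rejected(self):
        t = make_transcript([(0, 99)], [(0, 99)])
        with pytest.raises(TimingError):
            flag_excess_introns(t, (3, 1))
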