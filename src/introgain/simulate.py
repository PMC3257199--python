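"""Forward simulator for intron gain in TE-derived gene families.

Each simulated family is born intronless on the stem of a chosen
domestication node and exists in every leaf beneath it.  Introns are
then gained as a Poisson process along the branches of that subtree
(with an optional rate burst on one stem branch, emulating a
concentrated episode of gain in a single ancestor), each gain drawing a
region (5'UTR/CDS/3'UTR) from configurable weights, a position uniform
within the region, and a length from a log-normal model.  Existing
introns are lost per branch at a (low) loss rate, and all sequences
diverge under Jukes-Cantor.  Because exonic regions evolve without
indels, the emitted region alignments are gap-free by construction, so
homology recovery can be tested independently of alignment quality.

The simulation truth records every event, giving ground truth for
recovery tests of the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .gene_models import (GenomicInterval, TranscriptModel, write_gff3,
                          MIN_INTRON_LENGTH)
from .homology import RegionAlignment, write_region_alignment
from .timing import SpeciesTree

__all__ = [
    "SimulationConfig",
    "GainEvent",
    "SimulationTruth",
    "SimulationResult",
    "simulate",
    "branch_gain_counts",
    "default_tree",
]

_NT = np.array(list("ACGT"))


def default_tree() -> SpeciesTree:
    from .fixtures import load_species_tree

    return load_species_tree()


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults emulate the inferred history of Eutheria-specific
    domesticated genes: families born intronless on the placental stem,
    a burst of gain on that same stem, positions biased strongly to the
    5'UTR and CDS with rare 3'UTR gains, log-normal intron lengths
    spanning a few hundred to a few thousand nt with a heavy right
    tail, and rare losses.  Branch lengths are in units of 100 My.
    """

    tree: Optional[SpeciesTree] = None
    n_families: int = 50
    domestication_node: str = "Eutheria"
    gain_rate: float = 0.5  # events per branch-length unit per family
    burst_node: Optional[str] = "Eutheria"
    burst_multiplier: float = 10.0
    region_weights: dict = field(
        default_factory=lambda: {"UTR5": 0.55, "CDS": 0.40, "UTR3": 0.05}
    )
    length_mu_log: float = math.log(800.0)
    length_sigma_log: float = 1.0
    loss_rate: float = 0.005  # per existing intron per branch-length unit
    substitution_rate: float = 0.05  # per site per branch-length unit (JC)
    unknown_rate: float = 0.0
    seed: int = 0
    utr5_length: int = 600
    cds_length: int = 1200
    utr3_length: int = 400
    #: per-branch gain-rate overrides keyed by child-node label; permits
    #: exact ancestor-targeted scenarios (including zero-length branches)
    branch_rate_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.region_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region_weights sum to {total}, expected 1")
        for name in ("gain_rate", "burst_multiplier", "loss_rate",
                     "substitution_rate", "unknown_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cds_length % 3:
            raise ValueError("cds_length must be a multiple of 3")

    def resolved_tree(self) -> SpeciesTree:
        return self.tree if self.tree is not None else default_tree()


@dataclass
class GainEvent:
    family_id: str
    site_id: str
    region: str
    position: int  # region offset in ancestral (exonic) coordinates
    phase: Optional[int]
    gain_node: str  # child-end label of the branch carrying the gain
    length: int
    loss_branches: list[str] = field(default_factory=list)
    present_species: list[str] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)


@dataclass
class SimulationTruth:
    domestication_node: str
    families: list[str]
    events: list[GainEvent]
    censored: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append({
                "family_id": e.family_id,
                "site_id": e.site_id,
                "region": e.region,
                "position": e.position,
                "phase": "." if e.phase is None else e.phase,
                "gain_node": e.gain_node,
                "length": e.length,
                "loss_branches": ";".join(sorted(e.loss_branches)),
                "present_species": ",".join(sorted(e.present_species)),
            })
        return pd.DataFrame(rows, columns=[
            "family_id", "site_id", "region", "position", "phase",
            "gain_node", "length", "loss_branches", "present_species",
        ])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
        meta = pd.DataFrame({
            "family_id": self.families,
            "origin_node": self.domestication_node,
            "censored_species": [
                ",".join(sorted(self.censored.get(f, []))) for f in self.families
            ],
        })
        meta.to_csv(outdir / "truth_families.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "SimulationTruth":
        outdir = Path(outdir)
        meta = pd.read_csv(outdir / "truth_families.tsv", sep="\t",
                           keep_default_na=False)
        events_df = pd.read_csv(outdir / "truth_events.tsv", sep="\t",
                                keep_default_na=False)
        events = []
        for _, r in events_df.iterrows():
            events.append(GainEvent(
                family_id=str(r["family_id"]), site_id=str(r["site_id"]),
                region=str(r["region"]), position=int(r["position"]),
                phase=None if str(r["phase"]) == "." else int(r["phase"]),
                gain_node=str(r["gain_node"]), length=int(r["length"]),
                loss_branches=(str(r["loss_branches"]).split(";")
                               if str(r["loss_branches"]) else []),
                present_species=(str(r["present_species"]).split(",")
                                 if str(r["present_species"]) else []),
            ))
        censored = {
            str(r["family_id"]): (str(r["censored_species"]).split(",")
                                  if str(r["censored_species"]) else [])
            for _, r in meta.iterrows()
        }
        return cls(
            domestication_node=str(meta["origin_node"].iloc[0]) if len(meta)
            else "",
            families=[str(f) for f in meta["family_id"]],
            events=events,
            censored=censored,
        )


@dataclass
class SimulationResult:
    config: SimulationConfig
    transcripts: dict[str, list[TranscriptModel]]  # species -> models
    genomes: dict[str, dict[str, str]]  # species -> contig -> sequence
    alignments: list[RegionAlignment]
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# core machinery
# ---------------------------------------------------------------------------

def _edge_label(tree: SpeciesTree, node: dendropy.Node) -> str:
    label = tree.node_label(node)
    if label:
        return label
    return "+".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def _subtree_edges(tree: SpeciesTree, root_label: str):
    """Edges of the subtree at ``root_label``, stem first, preorder.

    Yields (child_node, label, length); the stem edge of the subtree
    root is included so gains can predate the crown node.
    """
    root = tree.node(root_label)
    for node in root.preorder_iter():
        length = node.edge.length if node.edge.length is not None else 0.0
        yield node, _edge_label(tree, node), float(length)


def _effective_rate(cfg: SimulationConfig, label: str) -> float:
    if label in cfg.branch_rate_overrides:
        return float(cfg.branch_rate_overrides[label])
    rate = cfg.gain_rate
    if cfg.burst_node is not None and label == cfg.burst_node:
        rate *= cfg.burst_multiplier
    return rate


def _region_lengths(cfg: SimulationConfig) -> dict[str, int]:
    return {"UTR5": cfg.utr5_length, "CDS": cfg.cds_length,
            "UTR3": cfg.utr3_length}


def _draw_family_gains(cfg: SimulationConfig, tree: SpeciesTree,
                       rng: np.random.Generator,
                       family_id: str) -> list[GainEvent]:
    """Poisson gains along the subtree, with distinct positions per family."""
    regions = list(cfg.region_weights)
    weights = np.array([cfg.region_weights[r] for r in regions])
    region_len = _region_lengths(cfg)
    taken: set[tuple[str, int]] = set()
    events: list[GainEvent] = []
    k = 0
    for node, label, length in _subtree_edges(tree, cfg.domestication_node):
        expected = _effective_rate(cfg, label) * length
        if label in cfg.branch_rate_overrides and length == 0.0:
            expected = float(cfg.branch_rate_overrides[label])
        n = rng.poisson(expected) if expected > 0 else 0
        for _ in range(n):
            region = regions[rng.choice(len(regions), p=weights)]
            for _try in range(1000):
                position = int(rng.integers(1, region_len[region]))
                if (region, position) not in taken:
                    break
            else:  # pragma: no cover - region saturated with introns
                continue
            taken.add((region, position))
            length_nt = max(MIN_INTRON_LENGTH,
                            int(round(rng.lognormal(cfg.length_mu_log,
                                                    cfg.length_sigma_log))))
            k += 1
            events.append(GainEvent(
                family_id=family_id,
                site_id=f"{family_id}_s{k}",
                region=region,
                position=position,
                phase=position % 3 if region == "CDS" else None,
                gain_node=label,
                length=length_nt,
            ))
    return events


def _apply_losses(cfg: SimulationConfig, tree: SpeciesTree,
                  rng: np.random.Generator, event: GainEvent) -> None:
    """Prune the intron in random subtrees below its gain branch."""
    gain = tree.node(event.gain_node) if event.gain_node in tree._by_label \
        else None
    if gain is None:  # unlabeled internal branch label
        raise ValueError(f"cannot resolve gain node {event.gain_node}")

    present: list[str] = []

    def walk(node: dendropy.Node) -> None:
        if node.is_leaf():
            present.append(node.taxon.label)
            return
        for child in node.child_nodes():
            length = float(child.edge.length or 0.0)
            p_lose = 1.0 - math.exp(-cfg.loss_rate * length) \
                if cfg.loss_rate > 0 else 0.0
            if p_lose > 0 and rng.random() < p_lose:
                event.loss_branches.append(_edge_label(tree, child))
            else:
                walk(child)

    walk(gain)
    event.present_species = sorted(present)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _jc_evolve(rng: np.random.Generator, seq: np.ndarray, rate: float,
               t: float) -> np.ndarray:
    """Jukes-Cantor: substitute each site w.p. 3/4(1-e^(-4rt/3))."""
    if rate <= 0 or t <= 0:
        return seq.copy()
    p = 0.75 * (1.0 - math.exp(-4.0 * rate * t / 3.0))
    hit = rng.random(seq.size) < p
    out = seq.copy()
    # substitute to one of the three other nucleotides
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _codes_to_str(seq: np.ndarray) -> str:
    return "".join(_NT[seq])


def _evolve_down(tree: SpeciesTree, rng: np.random.Generator,
                 root: dendropy.Node, ancestral: np.ndarray,
                 rate: float, include_root_stem: bool = False,
                 stem_length: float = 0.0) -> dict[str, np.ndarray]:
    """Evolve a sequence from ``root`` to every leaf beneath it."""
    out: dict[str, np.ndarray] = {}

    def walk(node: dendropy.Node, seq: np.ndarray) -> None:
        if node.is_leaf():
            out[node.taxon.label] = seq
            return
        for child in node.child_nodes():
            walk(child, _jc_evolve(rng, seq, rate,
                                   float(child.edge.length or 0.0)))

    start = _jc_evolve(rng, ancestral, rate, stem_length) \
        if include_root_stem else ancestral
    walk(root, start)
    return out


def _translate(nt_seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt_seq).translate())


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig,
             outdir: Optional[str | Path] = None) -> SimulationResult:
    """Run the forward simulation; optionally write GFF3/FASTA/alignments.

    All randomness flows from ``config.seed``.  With a fixed seed the
    result (and every written file) is bit-reproducible.
    """
    tree = config.resolved_tree()
    if config.domestication_node not in tree._by_label:
        raise ValueError(
            f"domestication_node {config.domestication_node!r} not in tree"
        )
    rng = np.random.default_rng(config.seed)
    dom = tree.node(config.domestication_node)
    species = sorted(tree.leaves_under(dom))
    region_len = _region_lengths(config)
    u, c, w = (region_len["UTR5"], region_len["CDS"], region_len["UTR3"])

    truth = SimulationTruth(
        domestication_node=config.domestication_node,
        families=[], events=[], censored={},
    )
    transcripts: dict[str, list[TranscriptModel]] = {sp: [] for sp in species}
    genomes: dict[str, dict[str, str]] = {sp: {} for sp in species}
    alignments: list[RegionAlignment] = []

    for fam_idx in range(config.n_families):
        family_id = f"fam{fam_idx:03d}"
        truth.families.append(family_id)
        strand = "+" if fam_idx % 2 == 0 else "-"

        # gains, losses
        events = _draw_family_gains(config, tree, rng, family_id)
        for event in events:
            _apply_losses(config, tree, rng, event)
        events = [e for e in events if e.present_species]

        # exonic sequence evolves from the domestication ancestor
        ancestral_exonic = _random_seq(rng, u + c + w)
        leaf_exonic = _evolve_down(tree, rng, dom, ancestral_exonic,
                                   config.substitution_rate)

        # intron sequences evolve from the gain branch downward
        for event in events:
            ancestral_intron = _random_seq(rng, event.length)
            gain_node = tree.node(event.gain_node)
            seqs = _evolve_down(tree, rng, gain_node, ancestral_intron,
                                config.substitution_rate)
            event.sequences = {
                sp: _codes_to_str(seqs[sp]) for sp in event.present_species
            }

        censored = sorted(
            sp for sp in species if rng.random() < config.unknown_rate
        )
        truth.censored[family_id] = censored
        truth.events.extend(events)

        visible = [sp for sp in species if sp not in censored]
        for sp in visible:
            model, contig_seq, contig = _realize_transcript(
                config, family_id, sp, strand, events, leaf_exonic[sp], rng
            )
            transcripts[sp].append(model)
            genomes[sp][contig] = contig_seq

        # gap-free region alignments (positions tracked exactly)
        exon_rows = {sp: _codes_to_str(leaf_exonic[sp]) for sp in visible}
        alignments.append(RegionAlignment(
            family_id, "UTR5",
            {sp: s[:u] for sp, s in exon_rows.items()}, "nucleotide"))
        alignments.append(RegionAlignment(
            family_id, "CDS",
            {sp: _translate(s[u:u + c]) for sp, s in exon_rows.items()},
            "protein"))
        alignments.append(RegionAlignment(
            family_id, "UTR3",
            {sp: s[u + c:] for sp, s in exon_rows.items()}, "nucleotide"))

    result = SimulationResult(config, transcripts, genomes, alignments, truth)
    if outdir is not None:
        _write_result(result, Path(outdir))
    return result


def _realize_transcript(cfg: SimulationConfig, family_id: str, species: str,
                        strand: str, events: list[GainEvent],
                        exonic: np.ndarray, rng: np.random.Generator):
    """Build one species' transcript model and its genomic contig."""
    u, c, w = cfg.utr5_length, cfg.cds_length, cfg.utr3_length
    tx_len = u + c + w
    offset_map = {"UTR5": 0, "CDS": u, "UTR3": u + c}
    mine = sorted(
        (e for e in events if species in e.present_species),
        key=lambda e: (offset_map[e.region] + e.position, e.site_id),
    )
    # exon segments between intron insertion points (transcript coords)
    points = [offset_map[e.region] + e.position for e in mine]
    segments = []
    prev = 0
    for p in points:
        segments.append((prev, p))
        prev = p
    segments.append((prev, tx_len))

    # assemble gene body in gene-forward coordinates
    flank = 200
    body_parts = []
    exon_fwd: list[tuple[int, int]] = []
    cursor = 0
    tx_seq = _codes_to_str(exonic)
    for (seg, event) in zip(segments, mine + [None]):
        lo, hi = seg
        body_parts.append(tx_seq[lo:hi])
        exon_fwd.append((cursor, cursor + (hi - lo)))
        cursor += hi - lo
        if event is not None:
            body_parts.append(event.sequences[species])
            cursor += event.length
    body = "".join(body_parts)
    span = len(body)

    contig = f"{species}_{family_id}"
    flank5 = _codes_to_str(_random_seq(rng, flank))
    flank3 = _codes_to_str(_random_seq(rng, flank))
    if strand == "+":
        contig_seq = flank5 + body + flank3
        gmap = lambda g0, g1: (flank + g0, flank + g1)
    else:
        contig_seq = flank5 + _revcomp(body) + flank3
        gmap = lambda g0, g1: (flank + span - g1, flank + span - g0)

    exons = [GenomicInterval(contig, *gmap(g0, g1), strand)
             for g0, g1 in exon_fwd]
    # CDS intervals: transcript window [u, u+c) intersected with exons
    cds = []
    tx_cursor = 0
    for (g0, g1), (t0, t1) in zip(
            exon_fwd, ((lo, hi) for lo, hi in segments)):
        lo = max(t0, u)
        hi = min(t1, u + c)
        if lo < hi:
            f0 = g0 + (lo - t0)
            f1 = g0 + (hi - t0)
            cds.append(GenomicInterval(contig, *gmap(f0, f1), strand))
    model = TranscriptModel(
        gene_id=family_id, species_id=species,
        exons=exons, cds=cds, strand=strand,
    )
    return model, contig_seq, contig


def _revcomp(seq: str) -> str:
    from .gene_models import revcomp

    return revcomp(seq)


def _write_result(result: SimulationResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, models in sorted(result.transcripts.items()):
        write_gff3(models, outdir / f"{sp}.gff3")
        with open(outdir / f"{sp}.fa", "w") as fh:
            for contig, seq in sorted(result.genomes[sp].items()):
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for aln in result.alignments:
        write_region_alignment(
            aln, aln_dir / f"{aln.family_id}_{aln.region_class}.afa"
        )
    result.truth.write(outdir / "truth")


def branch_gain_counts(config: SimulationConfig,
                       n_replicates: int) -> dict[str, np.ndarray]:
    """Per-branch gain counts over replicate families (calibration aid).

    Returns, for every branch of the domestication subtree (keyed by
    child-node label), the number of gains drawn on it in each of
    ``n_replicates`` independently simulated families.
    """
    tree = config.resolved_tree()
    rng = np.random.default_rng(config.seed)
    labels = [label for _, label, _ in
              _subtree_edges(tree, config.domestication_node)]
    counts = {label: np.zeros(n_replicates, dtype=int) for label in labels}
    for rep in range(n_replicates):
        for event in _draw_family_gains(config, tree, rng, f"rep{rep}"):
            counts[event.gain_node][rep] += 1
    return counts
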