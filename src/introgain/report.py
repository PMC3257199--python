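"""Pipeline orchestration and report generation.

Ties the stages together: extract introns from per-species gene
structures, project and cluster them into homologous sites, place gene
origins and per-site gains on the species tree, and summarize densities,
positional bias, sizes and sequence conservation into per-stage TSVs and
one versioned JSON summary.  Two input modes are supported: the packaged
fixture bundle (no gene structures; origins and tallies come from the
transcribed survey tables) and a directory produced by the simulator
(full round trip against the recorded truth).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import gene_models as gm
from . import homology as hm
from .conservation import intron_identity
from .timing import (SpeciesTree, GainLossScenario, place_gene_origin,
                     place_sites, tally_gains)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "positional_bias_table",
    "positional_bias_from_metadata",
    "recovery_report",
]

SCHEMA_VERSION = "1"
log = logging.getLogger("introgain")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    input_dir: Optional[Path] = None  # None -> packaged fixture bundle
    output_dir: Path = Path("introgain_out")
    tree_path: Optional[Path] = None
    repeats_path: Optional[Path] = None
    slack: int = 0
    identity_threshold: float = 70.0
    density_pooling: str = "pooled"  # pooled | per_gene_mean
    seed: int = 0
    conserve: bool = True  # run the pairwise-identity stage
    #: introns longer than this are skipped by the conservation stage
    #: (quadratic alignment cost; long introns are summarized by length only)
    conserve_max_nt: int = 5000
    conserve_max_pairs: int = 200

    def validate(self) -> None:
        if self.input_dir is not None:
            p = Path(self.input_dir)
            if not p.is_dir():
                raise PipelineError("config", f"input dir {p} does not exist")
            if not any(p.glob("*.gff3")):
                raise PipelineError(
                    "config", f"input dir {p} contains no *.gff3 gene structures"
                )
        if self.slack < 0:
            raise PipelineError("config", "slack must be >= 0")
        if not (0 < self.identity_threshold <= 100):
            raise PipelineError("config", "identity threshold must be in (0,100]")
        if self.density_pooling not in ("pooled", "per_gene_mean"):
            raise PipelineError("config", "density_pooling must be pooled or "
                                "per_gene_mean")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def positional_bias_table(introns: list[gm.Intron]) -> pd.DataFrame:
    """Counts and fractions of introns per region class."""
    order = ["UTR5", "CDS", "UTR3"]
    counts = {r: 0 for r in order}
    for i in introns:
        if i.region_class in counts:
            counts[i.region_class] += 1
    total = sum(counts.values())
    df = pd.DataFrame({
        "region": order,
        "count": [counts[r] for r in order],
        "fraction": [counts[r] / total if total else 0.0 for r in order],
    }).set_index("region")
    return df


def positional_bias_from_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Min/max per-region gain counts from fixture location annotations.

    A family whose location is "A/B" has introns in both regions; "A or
    B" in one of them (counted in the max of both, the min of neither).
    Families without printed counts contribute zero.
    """
    order = ["UTR5", "CDS", "UTR3"]
    lo = {r: 0 for r in order}
    hi = {r: 0 for r in order}
    families_any = {r: [] for r in order}
    for _, rec in meta.iterrows():
        loc = str(rec.get("intron_location", "") or "")
        if not loc or loc == "nan":
            continue
        either = " or " in loc
        regions = [t.strip() for t in
                   (loc.split(" or ") if either else loc.split("/"))]
        regions = [r for r in regions if r in order]
        if not regions:
            continue
        for r in regions:
            families_any[r].append(str(rec["family_id"]))
        if pd.isna(rec.get("intron_min")) or pd.isna(rec.get("intron_max")):
            continue
        n_min, n_max = int(rec["intron_min"]), int(rec["intron_max"])
        if either:
            for r in regions:
                hi[r] += n_max  # all introns could sit in this region
        elif len(regions) == 1:
            lo[regions[0]] += n_min
            hi[regions[0]] += n_max
        else:
            # both regions occupied: each holds at least one intron
            for r in regions:
                lo[r] += 1
                hi[r] += n_max - (len(regions) - 1)
    df = pd.DataFrame({
        "region": order,
        "count_min": [lo[r] for r in order],
        "count_max": [hi[r] for r in order],
        "n_families": [len(families_any[r]) for r in order],
        "families": [",".join(families_any[r]) for r in order],
    }).set_index("region")
    return df


def _size_quantiles(lengths: list[int]) -> dict[str, float]:
    if not lengths:
        return {}
    s = pd.Series(lengths, dtype=float)
    return {
        "n": int(s.size),
        "min": float(s.min()),
        "q25": float(s.quantile(0.25)),
        "median": float(s.quantile(0.5)),
        "q75": float(s.quantile(0.75)),
        "max": float(s.max()),
    }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute extract -> homologize -> time-gains -> stats -> conserve.

    Returns the JSON summary (also written to ``summary.json`` in the
    output directory, alongside the per-stage TSVs and a run log).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        if config.input_dir is None:
            summary = _run_fixture_mode(config, outdir)
        else:
            summary = _run_structure_mode(config, outdir)
    except PipelineError:
        failed_marker.write_text("pipeline failed; partial outputs retained\n")
        raise
    except Exception as exc:
        failed_marker.write_text(f"pipeline failed: {exc}\n")
        raise

    summary["schema_version"] = SCHEMA_VERSION
    summary["seed"] = config.seed
    summary["config_hash"] = _config_hash(config)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_log(config, outdir)
    return summary


def _config_hash(config: RunConfig) -> str:
    # the hash covers the analytic configuration, not where outputs land
    payload = json.dumps(
        {k: str(v) for k, v in vars(config).items() if k != "output_dir"},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_log(config: RunConfig, outdir: Path) -> None:
    from . import __version__

    with open(outdir / "run.log", "w") as fh:
        fh.write(f"introgain {__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"config_hash: {_config_hash(config)}\n")
        for k, v in sorted(vars(config).items()):
            fh.write(f"{k}: {v}\n")


def _load_tree(config: RunConfig) -> SpeciesTree:
    if config.tree_path is not None:
        return SpeciesTree.from_newick(str(config.tree_path))
    if config.input_dir is not None:
        cand = Path(config.input_dir) / "species_tree.nwk"
        if cand.exists():
            return SpeciesTree.from_newick(str(cand))
    from .fixtures import load_species_tree

    return load_species_tree()


def _run_fixture_mode(config: RunConfig, outdir: Path) -> dict:
    """Origins/tallies from the packaged transcribed-table bundle."""
    from .fixtures import (fixture_scenarios, load_family_metadata,
                           load_species_tree, package_paper_fixtures)
    from .timing import filter_eligible

    tree = load_species_tree()
    package_paper_fixtures(outdir / "fixtures")

    scenarios = fixture_scenarios(tree)
    tally = tally_gains(scenarios, tree)
    tally.to_csv(outdir / "per_node_tally.tsv", sep="\t")

    meta = load_family_metadata()
    eligibility = filter_eligible(list(meta.itertuples(index=False)))
    pd.DataFrame([vars(r) for r in eligibility]).to_csv(
        outdir / "eligibility.tsv", sep="\t", index=False
    )

    origins = pd.DataFrame(
        [{"family_id": sc.family_id, "origin_node": sc.origin_node,
          "progenitor_class": sc.progenitor_class} for sc in scenarios]
    )
    origins.to_csv(outdir / "gene_origin_placements.tsv", sep="\t", index=False)

    bias = positional_bias_from_metadata(meta)
    bias.to_csv(outdir / "positional_bias.tsv", sep="\t")

    by_node = {
        node: {
            "n_families_originating": int(row["n_families_originating"]),
            "n_intron_gains_min": int(row["n_intron_gains_min"]),
            "n_intron_gains_max": int(row["n_intron_gains_max"]),
        }
        for node, row in tally.iterrows()
    }
    eutheria = [sc for sc in scenarios if sc.origin_node == "Eutheria"]
    summary = {
        "mode": "fixtures",
        "per_node_tally": by_node,
        "eutheria_origin_families": len(eutheria),
        "eutheria_origin_by_class": {
            cls: sum(1 for sc in eutheria if sc.progenitor_class == cls)
            for cls in ("retroelement", "DNA_transposon")
        },
        "n_eligible_dna_transposon": sum(
            1 for r, m in zip(eligibility, meta.itertuples(index=False))
            if r.eligible and m.progenitor_class == "DNA_transposon"
        ),
        "positional_bias": {
            r: {"count_min": int(bias.at[r, "count_min"]),
                "count_max": int(bias.at[r, "count_max"]),
                "n_families": int(bias.at[r, "n_families"])}
            for r in bias.index
        },
    }
    return summary


def _run_structure_mode(config: RunConfig, outdir: Path) -> dict:
    indir = Path(config.input_dir)
    tree = _load_tree(config)

    # -- extract ----------------------------------------------------------
    stage = "extract"
    transcripts: dict[str, list[gm.TranscriptModel]] = {}
    introns_by_family: dict[str, list[tuple[str, gm.Intron]]] = {}
    all_introns: list[gm.Intron] = []
    try:
        for gff in sorted(indir.glob("*.gff3")):
            species = gff.stem
            models = gm.read_gene_structures(gff, species)
            transcripts[species] = models
            for model in models:
                for intron in gm.extract_introns(model):
                    introns_by_family.setdefault(model.gene_id, []).append(
                        (species, intron)
                    )
                    all_introns.append(intron)
    except gm.GeneStructureError as exc:
        raise PipelineError(stage, str(exc)) from exc
    _write_intron_table(all_introns, outdir / "introns.tsv")

    # -- homologize -------------------------------------------------------
    stage = "homologize"
    aln_dir = indir / "alignments"
    genomes = _load_genomes(indir)
    sites_by_family: dict[str, list[hm.IntronSite]] = {}
    species_with_data = sorted(transcripts)
    n_fallback = 0
    try:
        for family_id in sorted(introns_by_family):
            sites, used_fallback = _homologize_family(
                family_id, introns_by_family[family_id], aln_dir,
                species_with_data, config.slack, transcripts, genomes,
            )
            sites_by_family[family_id] = sites
            n_fallback += used_fallback
    except (hm.ProjectionError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc
    _write_site_matrix(sites_by_family, species_with_data,
                       outdir / "presence_matrix.tsv")

    # -- time-gains -------------------------------------------------------
    stage = "time-gains"
    scenarios: list[GainLossScenario] = []
    try:
        for family_id, sites in sorted(sites_by_family.items()):
            presence = {
                sp: (hm.PRESENT if any(m.gene_id == family_id
                                       for m in transcripts.get(sp, []))
                     else hm.ABSENT)
                for sp in tree.leaves()
            }
            for sp in tree.leaves():
                if sp not in transcripts:
                    presence[sp] = hm.UNKNOWN
            origin = place_gene_origin(tree, presence)
            scenarios.append(place_sites(tree, family_id, origin, sites))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    tally = tally_gains(scenarios, tree)
    tally.to_csv(outdir / "per_node_tally.tsv", sep="\t")
    _write_scenarios(scenarios, outdir / "scenarios.tsv")

    # -- stats ------------------------------------------------------------
    stage = "stats"
    ref_species = species_with_data[0] if species_with_data else None
    density = gm.gene_set_density(transcripts.get(ref_species, []))
    bias = positional_bias_table(all_introns)
    bias.to_csv(outdir / "positional_bias.tsv", sep="\t")
    sizes = _size_quantiles([i.length for i in all_introns])

    # -- conserve ---------------------------------------------------------
    stage = "conserve"
    conservation_summary = _conserve_stage(
        config, genomes, outdir, transcripts, sites_by_family
    )

    by_node = {
        str(node): {k: int(v) for k, v in row.items()}
        for node, row in tally.iterrows()
    }
    summary = {
        "mode": "structures",
        "n_species": len(transcripts),
        "n_families": len(introns_by_family),
        "n_introns": len(all_introns),
        "n_sites": sum(len(s) for s in sites_by_family.values()),
        # region alignments built by the lower-confidence pairwise fallback
        "n_fallback_alignments": n_fallback,
        "per_node_tally": by_node,
        "densities": {
            "reference_species": ref_species,
            "pooling": config.density_pooling,
            "density_cds": density.density_cds,
            "density_utr5": density.density_utr5,
            "kb_cds": density.kb_cds,
            "kb_utr5": density.kb_utr5,
        },
        "positional_bias": {
            r: {"count": int(bias.at[r, "count"]),
                "fraction": float(bias.at[r, "fraction"])}
            for r in bias.index
        },
        "intron_size_quantiles": sizes,
        "conservation": conservation_summary,
    }
    return summary


def _homologize_family(family_id, species_introns, aln_dir, species_with_data,
                       slack, transcripts, genomes
                       ) -> tuple[list[hm.IntronSite], int]:
    sites: list[hm.IntronSite] = []
    n_fallback = 0
    by_region: dict[str, list[tuple[str, gm.Intron]]] = {}
    for species, intron in species_introns:
        by_region.setdefault(intron.region_class, []).append((species, intron))
    for region, items in sorted(by_region.items()):
        aln_path = aln_dir / f"{family_id}_{region}.afa"
        alphabet = "protein" if region == "CDS" else "nucleotide"
        if aln_path.exists():
            aln = hm.read_region_alignment(aln_path, family_id, region,
                                           alphabet)
        else:
            aln = _fallback_region_alignment(
                family_id, region, alphabet, transcripts, genomes,
            )
            n_fallback += 1
            log.warning(
                "%s/%s: no precomputed alignment; using lower-confidence "
                "pairwise-to-reference fallback", family_id, region,
            )
        projections = []
        for species, intron in items:
            column, phase = hm.project_intron(aln, species, intron)
            projections.append((species, intron, column, phase))
        sites.extend(hm.cluster_sites(
            aln, projections, slack=slack, group_species=species_with_data,
        ))
    return sites, n_fallback


def _fallback_region_alignment(family_id, region, alphabet, transcripts,
                               genomes) -> hm.RegionAlignment:
    if not genomes:
        raise hm.ProjectionError(
            f"{family_id}: no {region} alignment supplied and no genome "
            f"FASTA to build a fallback from"
        )
    seqs: dict[str, str] = {}
    for sp in sorted(transcripts):
        if sp not in genomes:
            continue
        for model in transcripts[sp]:
            if model.gene_id != family_id:
                continue
            seq = gm.region_sequence(model, genomes[sp], region)
            if alphabet == "protein":
                from Bio.Seq import Seq

                seq = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
            if seq:
                seqs[sp] = seq
    if not seqs:
        raise hm.ProjectionError(
            f"{family_id}: no {region} sequences available for fallback "
            f"alignment"
        )
    return hm.fallback_reference_alignment(family_id, region, seqs,
                                           alphabet=alphabet)


def _load_genomes(indir: Path) -> dict[str, dict[str, str]]:
    from Bio import SeqIO

    genomes: dict[str, dict[str, str]] = {}
    for fa in sorted(indir.glob("*.fa")):
        genomes[fa.stem] = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(fa), "fasta")
        }
    return genomes


def _conserve_stage(config, genomes, outdir, transcripts, sites_by_family):
    if not config.conserve:
        return {"n_pairs": 0, "skipped": True}
    if not genomes:
        return {"n_pairs": 0}

    intron_lookup: dict[tuple[str, str, str, Optional[int], int], gm.Intron] = {}
    for sp, models in transcripts.items():
        for model in models:
            for intron in gm.extract_introns(model):
                key = (sp, model.gene_id, intron.region_class, intron.phase,
                       intron.region_offset)
                intron_lookup[key] = intron

    records = []
    for family_id, sites in sorted(sites_by_family.items()):
        for site in sites:
            present = sorted(sp for sp, st in site.states.items()
                             if st == hm.PRESENT)
            if len(present) < 2:
                continue
            seqs = {}
            for sp in present:
                intron = _site_intron(intron_lookup, sp, family_id, site)
                if intron is None or intron.length > config.conserve_max_nt:
                    continue
                seq = _fetch(genomes, sp, intron.interval)
                if seq:
                    seqs[sp] = seq
            ref = present[0]
            for other in present[1:]:
                if len(records) >= config.conserve_max_pairs:
                    break
                if ref in seqs and other in seqs:
                    rec = intron_identity(
                        seqs[ref], seqs[other], site_id=site.site_id,
                        species_a=ref, species_b=other,
                        threshold=config.identity_threshold,
                    )
                    records.append(rec)
    df = pd.DataFrame([vars(r) for r in records])
    df.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    if not records:
        return {"n_pairs": 0}
    return {
        "n_pairs": len(records),
        "mean_percent_identity": float(df["percent_identity"].mean()),
        "fraction_highly_conserved": float(
            (df["classification"] == "highly_conserved").mean()
        ),
        "identity_definition": "matches over non-terminal-gap alignment "
                               "columns, end-free pairwise alignment",
    }


def _site_intron(lookup, species, family_id, site) -> Optional[gm.Intron]:
    # reconstruct the species' region offset from the site column/phase
    for key, intron in lookup.items():
        sp, fam, region, phase, _off = key
        if sp != species or fam != family_id or region != site.region_class:
            continue
        if site.phase is not None and phase != site.phase:
            continue
        if _matches_column(intron, site):
            return intron
    return None


def _matches_column(intron: gm.Intron, site) -> bool:
    if site.region_class == "CDS":
        phase = intron.phase or 0
        residue = (intron.region_offset // 3 - 1 if phase == 0
                   else intron.region_offset // 3)
        return residue == site.column
    return intron.region_offset - 1 == site.column


def _fetch(genomes, species, interval: gm.GenomicInterval) -> Optional[str]:
    contig = genomes.get(species, {}).get(interval.chrom)
    if contig is None:
        return None
    seq = contig[interval.start:interval.end]
    if interval.strand == "-":
        seq = gm.revcomp(seq)
    return seq


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------

def _write_intron_table(introns: list[gm.Intron], path: Path) -> None:
    rows = [{
        "gene_id": i.gene_id, "species_id": i.species_id, "ordinal": i.ordinal,
        "chrom": i.interval.chrom, "start": i.interval.start,
        "end": i.interval.end, "strand": i.interval.strand,
        "length": i.length, "region_class": i.region_class,
        "region_offset": i.region_offset,
        "phase": "." if i.phase is None else i.phase,
    } for i in introns]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_site_matrix(sites_by_family, species, path: Path) -> None:
    frames = []
    for family_id, sites in sorted(sites_by_family.items()):
        if sites:
            frames.append(hm.site_matrix(sites, species))
    if frames:
        matrix = pd.concat(frames)
    else:
        matrix = pd.DataFrame(columns=species)
    matrix.index.name = "site_id"
    matrix.to_csv(path, sep="\t")


def _write_scenarios(scenarios, path: Path) -> None:
    rows = []
    for sc in scenarios:
        if sc.site_gains:
            for site_id, node in sorted(sc.site_gains.items()):
                rows.append({
                    "family_id": sc.family_id,
                    "origin_node": sc.origin_node,
                    "site_id": site_id,
                    "gain_node": node,
                    "loss_branches": ";".join(
                        sorted(sc.site_losses.get(site_id, set()))
                    ),
                })
        else:
            rows.append({
                "family_id": sc.family_id, "origin_node": sc.origin_node,
                "site_id": "", "gain_node": "", "loss_branches": "",
            })
    pd.DataFrame(rows, columns=[
        "family_id", "origin_node", "site_id", "gain_node", "loss_branches",
    ]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simulation round trip
# ---------------------------------------------------------------------------

def recovery_report(sim_dir: str | Path, out_dir: str | Path,
                    slack: int = 0, seed: int = 0,
                    conserve: bool = False) -> dict:
    """Run the pipeline on a simulation directory and compare with truth.

    Matches recovered sites to true gain events by (region, ancestral
    position) — reconstructable exactly because the simulated alignments
    are gap-free — and reports how many recovered gain nodes equal the
    true gain branch.
    """
    from .simulate import SimulationTruth

    sim_dir = Path(sim_dir)
    config = RunConfig(input_dir=sim_dir, output_dir=Path(out_dir), slack=slack,
                       seed=seed, conserve=conserve)
    run_pipeline(config)

    truth = SimulationTruth.read(sim_dir / "truth")
    true_by_key = {
        (e.family_id, e.region, e.position): e.gain_node for e in truth.events
    }
    scen = pd.read_csv(Path(out_dir) / "scenarios.tsv", sep="\t",
                       keep_default_na=False)
    n_sites = n_match = n_more_recent = n_other = 0
    tree = _load_tree(config)
    for _, row in scen.iterrows():
        site_id = str(row["site_id"])
        if not site_id:
            continue
        family_id, region, column, phase = _parse_site_id(site_id)
        position = _column_to_position(region, column, phase)
        key = (family_id, region, position)
        if key not in true_by_key:
            continue
        n_sites += 1
        true_node, found_node = true_by_key[key], str(row["gain_node"])
        if found_node == true_node:
            n_match += 1
        elif tree.is_ancestor_or_equal(tree.node(true_node),
                                       tree.node(found_node)):
            n_more_recent += 1
        else:
            n_other += 1
    return {
        "n_true_events": len(truth.events),
        "n_recovered_sites": n_sites,
        "n_gain_node_match": n_match,
        "n_more_recent_than_truth": n_more_recent,
        "n_ancient_or_conflicting": n_other,
        "recovery_fraction": n_match / n_sites if n_sites else 0.0,
    }


def _parse_site_id(site_id: str):
    family_id, region, column, phase = site_id.rsplit(":", 3)
    return (family_id, region, int(column),
            None if phase == "." else int(phase))


def _column_to_position(region: str, column: int, phase) -> int:
    if region == "CDS":
        phase = phase or 0
        return 3 * (column + 1) if phase == 0 else 3 * column + phase
    return column + 1
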