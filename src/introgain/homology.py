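"""Intron-position homology across orthologs via alignment projection.

CDS introns are compared through protein alignments of the coding
region, with codon phase as a separate equality requirement; UTR introns
through nucleotide alignments of the UTR.  Projected positions are
clustered into homologous intron sites, and each species in the group is
assigned a present / absent / unknown state per site.  A species counts
as *absent* only when its alignment row actually covers the projected
column with sequence on both flanks; otherwise the state is *unknown*
(mirroring "incomplete" cells in low-coverage genomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .gene_models import Intron, REGION_CDS

__all__ = [
    "RegionAlignment",
    "IntronSite",
    "project_intron",
    "cluster_sites",
    "site_matrix",
    "matrix_to_states",
    "fallback_reference_alignment",
    "read_region_alignment",
    "write_region_alignment",
]

#: non-gap nucleotides/residues required on each side of a projected
#: column before a species may be scored 'absent' rather than 'unknown'
DEFAULT_FLANK = 10

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"
_STATE_CODE = {PRESENT: "P", ABSENT: "A", UNKNOWN: "U"}
_CODE_STATE = {v: k for k, v in _STATE_CODE.items()}


class ProjectionError(ValueError):
    pass


@dataclass
class RegionAlignment:
    """A multiple alignment of one region (UTR5/CDS/UTR3) of one family."""

    family_id: str
    region_class: str
    rows: dict[str, str]
    alphabet: str  # protein | nucleotide
    #: "precomputed" for user-supplied alignments; the internal pairwise
    #: fallback is flagged lower-confidence
    provenance: str = "precomputed"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.family_id}/{self.region_class}: unequal row lengths"
            )

    def ungapped_length(self, species_id: str) -> int:
        return sum(1 for c in self.rows[species_id] if c != "-")

    def column_of(self, species_id: str, ungapped_index: int) -> int:
        """Alignment column holding this species' ungapped residue index.

        Index -1 (no residue 5' of the insertion point) maps to column -1.
        """
        if ungapped_index < 0:
            return -1
        seen = -1
        for col, ch in enumerate(self.rows[species_id]):
            if ch != "-":
                seen += 1
                if seen == ungapped_index:
                    return col
        raise ProjectionError(
            f"{self.family_id}: ungapped index {ungapped_index} beyond "
            f"{species_id} row ({seen + 1} residues)"
        )


@dataclass
class IntronSite:
    """A homologous intron position with per-species presence states."""

    family_id: str
    region_class: str
    column: int
    phase: Optional[int]
    states: dict[str, str] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.site_id == "":
            ph = "." if self.phase is None else str(self.phase)
            self.site_id = f"{self.family_id}:{self.region_class}:{self.column}:{ph}"


def project_intron(aln: RegionAlignment, species_id: str,
                   i: Intron) -> tuple[int, Optional[int]]:
    """Project an intron into alignment coordinates.

    Returns the alignment column of the residue/nucleotide immediately
    5' of the insertion point (the residue *containing* the point for
    phase-1/2 CDS introns), plus the codon phase for CDS introns.
    """
    if i.region_class != aln.region_class:
        raise ProjectionError(
            f"{i.gene_id} intron {i.ordinal}: region {i.region_class} does "
            f"not match alignment region {aln.region_class}"
        )
    if species_id not in aln.rows:
        raise ProjectionError(f"no alignment row for species {species_id}")
    if aln.region_class == REGION_CDS and aln.alphabet == "protein":
        phase = i.phase if i.phase is not None else i.region_offset % 3
        if phase == 0:
            residue = i.region_offset // 3 - 1  # insertion between codons
        else:
            residue = i.region_offset // 3  # insertion inside this codon
        index = residue
    else:
        phase = i.phase
        index = i.region_offset - 1  # nucleotide immediately 5'
    try:
        column = aln.column_of(species_id, index)
    except ProjectionError as exc:
        raise ProjectionError(
            f"{i.gene_id} intron {i.ordinal}: {exc}"
        ) from exc
    return column, phase


def _run_ok(row: str, column: int, flank: int) -> bool:
    """Gap-free sequence within ``flank`` columns on each side of ``column``."""
    left = row[max(0, column + 1 - flank): column + 1]
    right = row[column + 1: column + 1 + flank]
    return "-" not in left and "-" not in right


def cluster_sites(aln: RegionAlignment,
                  projections: list[tuple[str, Intron, int, Optional[int]]],
                  slack: int = 0,
                  group_species: Optional[list[str]] = None,
                  incomplete: Optional[set[str]] = None,
                  flank: int = DEFAULT_FLANK) -> list[IntronSite]:
    """Cluster projected introns into homologous sites.

    Two introns share a site iff they have the same region class, equal
    phase (CDS), and columns within ``slack`` (single-linkage, merged
    deterministically left to right).  Species with alignment data but no
    intron at a site are *absent* when their row covers the column with
    ``flank`` residues of sequence on each side, else *unknown*; species
    flagged ``incomplete`` (or lacking a row) are always *unknown*.
    """
    incomplete = incomplete or set()
    if group_species is None:
        group_species = sorted(set(aln.rows) | {p[0] for p in projections})

    keyed = sorted(projections, key=lambda p: (p[3] is not None, p[3] or 0, p[2],
                                               p[0], p[1].ordinal))
    clusters: list[list[tuple[str, Intron, int, Optional[int]]]] = []
    for proj in keyed:
        placed = False
        for cl in clusters:
            if cl[0][3] != proj[3]:
                continue
            if any(abs(proj[2] - q[2]) <= slack for q in cl):
                cl.append(proj)
                placed = True
                break
        if not placed:
            clusters.append([proj])

    sites: list[IntronSite] = []
    for cl in clusters:
        species_here = [p[0] for p in cl]
        dupes = {s for s in species_here if species_here.count(s) > 1}
        if dupes:
            raise ValueError(
                f"{aln.family_id}: species {sorted(dupes)} contribute more "
                f"than one intron to a single site (annotation duplicates?)"
            )
        column = min(p[2] for p in cl)
        site = IntronSite(
            family_id=aln.family_id,
            region_class=aln.region_class,
            column=column,
            phase=cl[0][3],
        )
        for sp in group_species:
            if sp in species_here:
                site.states[sp] = PRESENT
                intron = next(p[1] for p in cl if p[0] == sp)
                site.lengths[sp] = intron.length
            elif sp in incomplete or sp not in aln.rows:
                site.states[sp] = UNKNOWN
            elif column >= 0 and _run_ok(aln.rows[sp], column, flank):
                site.states[sp] = ABSENT
            elif column < 0 and "-" not in aln.rows[sp][:flank]:
                site.states[sp] = ABSENT
            else:
                site.states[sp] = UNKNOWN
        sites.append(site)
    sites.sort(key=lambda s: (s.phase is not None, s.phase or 0, s.column))
    return sites


def site_matrix(sites: list[IntronSite],
                species_order: list[str]) -> pd.DataFrame:
    """Three-state presence matrix: rows = sites, columns = species (P/A/U)."""
    data = {}
    index = []
    for site in sites:
        index.append(site.site_id)
        for sp in species_order:
            data.setdefault(sp, []).append(
                _STATE_CODE[site.states.get(sp, UNKNOWN)]
            )
    return pd.DataFrame(data, index=index, columns=species_order, dtype="string")


def matrix_to_states(matrix: pd.DataFrame) -> dict[str, dict[str, str]]:
    """Inverse of :func:`site_matrix`: site_id -> species -> state."""
    return {
        site_id: {sp: _CODE_STATE[str(matrix.at[site_id, sp])]
                  for sp in matrix.columns}
        for site_id in matrix.index
    }


# ---------------------------------------------------------------------------
# fallback alignment (no precomputed MSA supplied)
# ---------------------------------------------------------------------------

def fallback_reference_alignment(family_id: str, region_class: str,
                                 seqs: dict[str, str],
                                 reference: Optional[str] = None,
                                 alphabet: str = "nucleotide"
                                 ) -> RegionAlignment:
    """Build a star alignment of region sequences around a reference.

    Each species is aligned pairwise to the reference (the first listed
    species by default) and the pairwise alignments are threaded into
    one multiple alignment; species insertions relative to the
    reference open gap columns in every other row.  This is a
    lower-confidence substitute for a genomic multiple alignment and is
    flagged as such in ``provenance``.
    """
    from Bio import Align

    if not seqs:
        raise ValueError(f"{family_id}: no sequences to align")
    species = list(seqs)
    reference = reference or species[0]
    if reference not in seqs:
        raise ValueError(f"{family_id}: reference {reference} has no sequence")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0

    ref_seq = seqs[reference]
    # msa columns: each is dict species -> char; ref_col[i] = column of ref residue i
    columns: list[dict[str, str]] = [{reference: ch} for ch in ref_seq]
    ref_col = list(range(len(ref_seq)))

    for sp in species:
        if sp == reference:
            continue
        if not seqs[sp]:
            continue
        alignment = aligner.align(ref_seq, seqs[sp])[0]
        ra, sa = str(alignment[0]), str(alignment[1])
        ref_i = 0
        insert_at = 0  # column position after the last placed ref residue
        for cr, cs in zip(ra, sa):
            if cr != "-":
                col = ref_col[ref_i]
                if cs != "-":
                    columns[col][sp] = cs
                ref_i += 1
                insert_at = col + 1
            else:
                # species insertion: open a fresh gap column for everyone
                columns.insert(insert_at, {sp: cs})
                for j in range(len(ref_col)):
                    if ref_col[j] >= insert_at:
                        ref_col[j] += 1
                insert_at += 1

    rows = {
        sp: "".join(col.get(sp, "-") for col in columns)
        for sp in species if seqs[sp]
    }
    return RegionAlignment(family_id, region_class, rows, alphabet,
                           provenance="fallback_pairwise_to_reference")


# ---------------------------------------------------------------------------
# aligned-FASTA I/O
# ---------------------------------------------------------------------------

def read_region_alignment(path, family_id: str, region_class: str,
                          alphabet: str = "nucleotide") -> RegionAlignment:
    from Bio import SeqIO

    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise ValueError(f"{path}: no sequences")
    return RegionAlignment(family_id, region_class, rows, alphabet)


def write_region_alignment(aln: RegionAlignment, path) -> None:
    with open(path, "w") as fh:
        for sp, seq in aln.rows.items():
            fh.write(f">{sp}\n{seq}\n")
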