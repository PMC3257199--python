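"""Gene-structure domain types, GFF3/BED12 I/O, intron extraction and densities.

Domesticated genes descend from intronless transposable-element coding
sequences, so every intron found in one is a de novo gain.  This module
provides the coordinate substrate for locating those gains: transcript
models in 0-based half-open genomic coordinates, intron extraction from
exon gaps, classification of each intron into 5'UTR / CDS / 3'UTR by its
position in transcription coordinates, codon phase for coding introns,
and intron densities per kilobase of region sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "Intron",
    "OrthologGroup",
    "GeneSetDensity",
    "MIN_INTRON_LENGTH",
    "read_gene_structures",
    "write_gff3",
    "write_bed12",
    "extract_introns",
    "classify_intron",
    "cds_phase",
    "gene_set_density",
]

#: Exon gaps shorter than this are treated as annotation artifacts.
MIN_INTRON_LENGTH = 4

REGION_UTR5 = "UTR5"
REGION_CDS = "CDS"
REGION_UTR3 = "UTR3"
REGION_NONCODING = "noncoding"


class GeneStructureError(ValueError):
    """Raised for malformed or inconsistent gene-structure input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based start (inclusive), end exclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GeneStructureError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GeneStructureError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One species' exon/CDS structure for one gene.

    ``exons`` and ``cds`` are kept in *transcription* order: ascending
    genomic coordinates on the plus strand, descending on the minus
    strand.  Intervals themselves always satisfy start < end.
    """

    gene_id: str
    species_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.exons:
            raise GeneStructureError(f"{self.gene_id}: transcript has no exons")
        self.validate()

    # -- derived quantities ------------------------------------------------

    def validate(self) -> None:
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise GeneStructureError(
                    f"{self.gene_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        expected = sorted(genomic, key=lambda e: e.start, reverse=self.strand == "-")
        if list(self.exons) != expected:
            raise GeneStructureError(
                f"{self.gene_id}: exons not in transcription order"
            )
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise GeneStructureError(
                    f"{self.gene_id}: CDS {c.start}-{c.end} outside exons"
                )
        if self.cds_length and self.cds_length % 3:
            warnings.warn(
                f"{self.gene_id}: CDS length {self.cds_length} not a multiple "
                f"of 3 (remainder {self.cds_length % 3})",
                stacklevel=2,
            )

    @property
    def exon_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(c.length for c in self.cds)

    @property
    def span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.exons[0].chrom, lo, hi, self.strand)

    def _cds_bounds_tx(self) -> Optional[tuple[int, int]]:
        """CDS interval [start, end) in transcript coordinates, or None."""
        if not self.cds:
            return None
        positions = []
        for c in self.cds:
            positions.append(self._to_tx(c.start if self.strand == "+" else c.end - 1))
            positions.append(self._to_tx(c.end - 1 if self.strand == "+" else c.start))
        return min(positions), max(positions) + 1

    def _to_tx(self, gpos: int) -> int:
        """Map a genomic position (on an exon) to transcript coordinates."""
        tx = 0
        for e in self.exons:
            if e.start <= gpos < e.end:
                if self.strand == "+":
                    return tx + (gpos - e.start)
                return tx + (e.end - 1 - gpos)
            tx += e.length
        raise GeneStructureError(
            f"{self.gene_id}: genomic position {gpos} not exonic"
        )

    def region_lengths(self) -> dict[str, int]:
        """Exonic nucleotides per region (UTR5/CDS/UTR3) in transcript order."""
        bounds = self._cds_bounds_tx()
        total = self.exon_length
        if bounds is None:
            return {REGION_UTR5: 0, REGION_CDS: 0, REGION_UTR3: 0,
                    REGION_NONCODING: total}
        lo, hi = bounds
        return {REGION_UTR5: lo, REGION_CDS: hi - lo, REGION_UTR3: total - hi,
                REGION_NONCODING: 0}


@dataclass
class Intron:
    """A located, classified, phased intron."""

    gene_id: str
    species_id: str
    ordinal: int  # 1-based, transcription order
    interval: GenomicInterval
    region_class: str
    region_offset: int
    phase: Optional[int] = None

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class OrthologGroup:
    """A gene family across species, with TE provenance metadata."""

    family_id: str
    progenitor_class: str  # retroelement | DNA_transposon
    origin_route: str  # whole_TE | fusion_3prime | DBD_shuffle
    members: dict[str, TranscriptModel] = field(default_factory=dict)
    fusion_exception: bool = False  # SCAND3-style retroelement fusion


@dataclass
class GeneSetDensity:
    n_introns_cds: int
    n_introns_utr5: int
    kb_cds: float
    kb_utr5: float
    density_cds: float
    density_utr5: float
    per_gene: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _choose_transcript(candidates: list[TranscriptModel],
                       ids: list[str]) -> TranscriptModel:
    # longest CDS, then longest exon sum, then lexicographic transcript id
    order = sorted(
        range(len(candidates)),
        key=lambda k: (-candidates[k].cds_length, -candidates[k].exon_length, ids[k]),
    )
    return candidates[order[0]]


def read_gene_structures(path: str | Path, species_id: str) -> list[TranscriptModel]:
    """Read transcript models from a GFF3 or BED12 file.

    One transcript is chosen per gene (longest CDS, ties by exon length,
    then transcript id).  Minus-strand transcripts are normalized so exon
    order follows transcription.
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line
                break
    if first and len(first.rstrip("\n").split("\t")) == 12:
        return _read_bed12(path, species_id)
    return _read_gff3(path, species_id)


def _read_gff3(path: Path, species_id: str) -> list[TranscriptModel]:
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises various parse errors
        raise GeneStructureError(f"{path}: GFF3 parse error: {exc}") from exc

    models: list[TranscriptModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        candidates, ids = [], []
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parents = mrnas if mrnas else [gene]
        for parent in parents:
            exons = [
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
                for f in db.children(parent, featuretype="exon", order_by="start")
            ]
            cds = [
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
                for f in db.children(parent, featuretype="CDS", order_by="start")
            ]
            if not exons:
                continue
            strand = parent.strand
            if strand == "-":
                exons = exons[::-1]
                cds = cds[::-1]
            try:
                models_id = gene.id
                candidates.append(TranscriptModel(
                    gene_id=models_id, species_id=species_id,
                    exons=exons, cds=cds, strand=strand,
                ))
                ids.append(parent.id)
            except GeneStructureError as exc:
                raise GeneStructureError(f"{path}: gene {gene.id}: {exc}") from exc
        if candidates:
            models.append(_choose_transcript(candidates, ids))
    return models


def _read_bed12(path: Path, species_id: str) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise GeneStructureError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(f)}"
                )
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise GeneStructureError(f"{path}:{lineno}: block count mismatch")
            exons = [
                GenomicInterval(chrom, chrom_start + s, chrom_start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            cds = []
            if thick_end > thick_start:
                for e in exons:
                    lo, hi = max(e.start, thick_start), min(e.end, thick_end)
                    if lo < hi:
                        cds.append(GenomicInterval(chrom, lo, hi, strand))
            if strand == "-":
                exons = exons[::-1]
                cds = cds[::-1]
            models.append(TranscriptModel(
                gene_id=name, species_id=species_id,
                exons=exons, cds=cds, strand=strand,
            ))
    return models


def write_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GFF3 (gene/mRNA/exon/CDS, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in models:
            span = t.span
            chrom = span.chrom
            fh.write(
                f"{chrom}\tintrogain\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{t.strand}\t.\tID={t.gene_id}\n"
            )
            tid = f"{t.gene_id}.t1"
            fh.write(
                f"{chrom}\tintrogain\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{t.strand}\t.\tID={tid};Parent={t.gene_id}\n"
            )
            for e in sorted(t.exons, key=lambda x: x.start):
                fh.write(
                    f"{chrom}\tintrogain\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\tParent={tid}\n"
                )
            for c in sorted(t.cds, key=lambda x: x.start):
                fh.write(
                    f"{chrom}\tintrogain\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{t.strand}\t0\tParent={tid}\n"
                )


def write_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in models:
            exons = sorted(t.exons, key=lambda e: e.start)
            span = t.span
            if t.cds:
                thick_start = min(c.start for c in t.cds)
                thick_end = max(c.end for c in t.cds)
            else:
                thick_start = thick_end = span.start
            sizes = ",".join(str(e.length) for e in exons)
            starts = ",".join(str(e.start - span.start) for e in exons)
            fh.write(
                f"{span.chrom}\t{span.start}\t{span.end}\t{t.gene_id}\t0\t"
                f"{t.strand}\t{thick_start}\t{thick_end}\t0\t{len(exons)}\t"
                f"{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Intron extraction and classification
# ---------------------------------------------------------------------------

def extract_introns(t: TranscriptModel) -> list[Intron]:
    """One intron per gap between consecutive exons, in transcription order.

    Gaps shorter than ``MIN_INTRON_LENGTH`` (too short for donor and
    acceptor dinucleotides) are dropped with a warning.
    """
    introns: list[Intron] = []
    ordinal = 0
    for a, b in zip(t.exons, t.exons[1:]):
        if t.strand == "+":
            lo, hi = a.end, b.start
        else:
            lo, hi = b.end, a.start
        gap = hi - lo
        if gap < MIN_INTRON_LENGTH:
            warnings.warn(
                f"{t.gene_id}: dropping {gap}-nt exon gap at "
                f"{t.exons[0].chrom}:{lo} (< {MIN_INTRON_LENGTH} nt)",
                stacklevel=2,
            )
            continue
        ordinal += 1
        intron = Intron(
            gene_id=t.gene_id,
            species_id=t.species_id,
            ordinal=ordinal,
            interval=GenomicInterval(a.chrom, lo, hi, t.strand),
            region_class=REGION_NONCODING,
            region_offset=0,
        )
        _classify_in_place(t, intron)
        introns.append(intron)
    return introns


def _insertion_point_tx(t: TranscriptModel, i: Intron) -> int:
    """Transcript coordinate of the intron's insertion point (exonic nt 5')."""
    tx = 0
    for e in t.exons:
        if t.strand == "+" and e.end == i.interval.start:
            return tx + e.length
        if t.strand == "-" and e.start == i.interval.end:
            return tx + e.length
        tx += e.length
    raise GeneStructureError(
        f"{t.gene_id}: intron {i.ordinal} does not abut an exon boundary"
    )


def _classify_in_place(t: TranscriptModel, i: Intron) -> None:
    pos = _insertion_point_tx(t, i)
    bounds = t._cds_bounds_tx()
    if bounds is None:
        warnings.warn(
            f"{t.gene_id}: no CDS annotated; intron {i.ordinal} classified "
            f"'noncoding'", stacklevel=3,
        )
        i.region_class = REGION_NONCODING
        i.region_offset = pos
        i.phase = None
        return
    lo, hi = bounds
    if pos <= lo:
        # no coding nucleotide 5' of the intron -> 5' UTR
        i.region_class = REGION_UTR5
        i.region_offset = pos
        i.phase = None
    elif pos < hi:
        i.region_class = REGION_CDS
        i.region_offset = pos - lo
        i.phase = (pos - lo) % 3
    else:
        i.region_class = REGION_UTR3
        i.region_offset = pos - hi
        i.phase = None


def classify_intron(t: TranscriptModel, i: Intron) -> str:
    """Region class of an intron: UTR5, CDS, UTR3, or 'noncoding'.

    An intron whose flanking exonic sequence straddles the start codon is
    CDS only if at least one coding nucleotide lies on each side;
    otherwise it belongs to the adjacent UTR.
    """
    _classify_in_place(t, i)
    return i.region_class


def cds_phase(t: TranscriptModel, i: Intron) -> int:
    """Phase of a CDS intron: coding nucleotides 5' of it, mod 3."""
    if classify_intron(t, i) != REGION_CDS:
        raise GeneStructureError(
            f"{t.gene_id}: cds_phase called on {i.region_class} intron"
        )
    assert i.phase is not None
    return i.phase


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def transcript_sequence(t: TranscriptModel, contigs: dict[str, str]) -> str:
    """Spliced transcript sequence (transcription orientation)."""
    parts = []
    for e in t.exons:
        piece = contigs[e.chrom][e.start:e.end]
        parts.append(revcomp(piece) if t.strand == "-" else piece)
    return "".join(parts)


def region_sequence(t: TranscriptModel, contigs: dict[str, str],
                    region: str) -> str:
    """Exonic sequence of one region (UTR5/CDS/UTR3) of a transcript."""
    tx = transcript_sequence(t, contigs)
    bounds = t._cds_bounds_tx()
    if bounds is None:
        if region == REGION_NONCODING:
            return tx
        return ""
    lo, hi = bounds
    if region == REGION_UTR5:
        return tx[:lo]
    if region == REGION_CDS:
        return tx[lo:hi]
    if region == REGION_UTR3:
        return tx[hi:]
    return ""


def gene_set_density(genes: list[TranscriptModel]) -> GeneSetDensity:
    """Pooled intron densities over a gene set.

    Primary figures are pooled: total introns divided by total region
    kilobases across the set.  Per-gene densities are retained in
    ``per_gene`` for transparency.
    """
    n_cds = n_utr5 = 0
    bp_cds = bp_utr5 = 0
    per_gene: dict[str, dict[str, float]] = {}
    for t in genes:
        introns = extract_introns(t)
        lens = t.region_lengths()
        g_cds = sum(1 for i in introns if i.region_class == REGION_CDS)
        g_utr5 = sum(1 for i in introns if i.region_class == REGION_UTR5)
        n_cds += g_cds
        n_utr5 += g_utr5
        bp_cds += lens[REGION_CDS]
        bp_utr5 += lens[REGION_UTR5]
        per_gene[t.gene_id] = {
            "n_introns_cds": g_cds,
            "n_introns_utr5": g_utr5,
            "kb_cds": lens[REGION_CDS] / 1000.0,
            "kb_utr5": lens[REGION_UTR5] / 1000.0,
            "density_cds": (g_cds / (lens[REGION_CDS] / 1000.0)
                            if lens[REGION_CDS] else 0.0),
            "density_utr5": (g_utr5 / (lens[REGION_UTR5] / 1000.0)
                             if lens[REGION_UTR5] else 0.0),
        }

    def _density(n: int, bp: int, region: str) -> float:
        if bp == 0:
            if n:
                raise GeneStructureError(
                    f"{n} {region} introns but zero total {region} length"
                )
            if genes:
                warnings.warn(f"zero total {region} length", stacklevel=2)
            return 0.0
        return n / (bp / 1000.0)

    return GeneSetDensity(
        n_introns_cds=n_cds,
        n_introns_utr5=n_utr5,
        kb_cds=bp_cds / 1000.0,
        kb_utr5=bp_utr5 / 1000.0,
        density_cds=_density(n_cds, bp_cds, "CDS"),
        density_utr5=_density(n_utr5, bp_utr5, "UTR5"),
        per_gene=per_gene,
    )
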