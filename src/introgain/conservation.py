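"""Intron sequence conservation and repeat (TE) occupancy.

Pairwise percent identity between orthologous intron sequences is
computed from a semi-global (end-free) nucleotide alignment: matches
divided by alignment columns, excluding the terminal-gap overhangs.
Introns at or above the identity threshold (default 70%, the conserved
band observed across the placental superorders) are classified as
highly conserved.  Repeat occupancy consumes precomputed annotations
(BED or RepeatMasker .out) and reports the merged masked fraction of
each intron; RepeatMasker itself is never executed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align

from .gene_models import GenomicInterval, Intron

__all__ = [
    "ConservationRecord",
    "RepeatOccupancy",
    "IDENTITY_THRESHOLD",
    "intron_identity",
    "repeat_occupancy",
    "read_repeat_annotations",
]

IDENTITY_THRESHOLD = 70.0

#: conventional nucleotide scoring: match +1, mismatch -1, open -2, extend -1
DEFAULT_SCORING = {"match": 1.0, "mismatch": -1.0,
                   "open": -2.0, "extend": -1.0}


@dataclass
class ConservationRecord:
    site_id: str
    species_a: str
    species_b: str
    percent_identity: float
    aligned_length: int
    classification: str  # highly_conserved | not_highly_conserved


@dataclass
class RepeatOccupancy:
    intron_id: str
    intron_length: int
    masked_nt: int
    masked_fraction: float
    repeat_classes: dict[str, int] = field(default_factory=dict)


def _aligner(scoring: dict) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    aligner.open_gap_score = scoring["open"]
    aligner.extend_gap_score = scoring["extend"]
    # end-free: overhangs cost nothing (semi-global)
    try:
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:  # older Bio.Align attribute names
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def intron_identity(seq_a: str, seq_b: str, *,
                    site_id: str = "", species_a: str = "a",
                    species_b: str = "b",
                    threshold: float = IDENTITY_THRESHOLD,
                    scoring: dict | None = None) -> ConservationRecord:
    """Percent identity of two intron sequences under end-free alignment.

    Identity = matches / alignment columns excluding terminal-gap
    overhang columns, x 100.  The computation is symmetric in its two
    sequences (the pair is ordered canonically before aligning).
    """
    seq_a, seq_b = str(seq_a).upper(), str(seq_b).upper()
    if not seq_a or not seq_b:
        raise ValueError("intron_identity requires two nonempty sequences")
    scoring = scoring or DEFAULT_SCORING
    # canonical order makes the score path, hence the identity, symmetric
    s1, s2 = sorted((seq_a, seq_b))
    alignment = _aligner(scoring).align(s1, s2)[0]
    row1, row2 = str(alignment[0]), str(alignment[1])
    start = max(_lead_gap(row1), _lead_gap(row2))
    stop = len(row1) - max(_tail_gap(row1), _tail_gap(row2))
    span1, span2 = row1[start:stop], row2[start:stop]
    columns = stop - start
    matches = sum(1 for x, y in zip(span1, span2) if x == y and x != "-")
    pid = 100.0 * matches / columns if columns else 0.0
    return ConservationRecord(
        site_id=site_id, species_a=species_a, species_b=species_b,
        percent_identity=pid, aligned_length=columns,
        classification=("highly_conserved" if pid >= threshold
                        else "not_highly_conserved"),
    )


def _lead_gap(row: str) -> int:
    return len(row) - len(row.lstrip("-"))


def _tail_gap(row: str) -> int:
    return len(row) - len(row.rstrip("-"))


# ---------------------------------------------------------------------------
# repeat occupancy
# ---------------------------------------------------------------------------

def merge_intervals(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals."""
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(pairs):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def repeat_occupancy(i: Intron,
                     repeats: list[tuple[GenomicInterval, str]]) -> RepeatOccupancy:
    """Masked fraction of an intron under a set of repeat annotations.

    Repeats are intersected with the intron interval and overlaps merged
    before summing, so nothing is double-counted; per-class subtotals
    are merged within each class.
    """
    iv = i.interval
    clipped: list[tuple[int, int]] = []
    by_class: dict[str, list[tuple[int, int]]] = {}
    for rep, cls in repeats:
        if rep.chrom != iv.chrom:
            continue
        lo, hi = max(rep.start, iv.start), min(rep.end, iv.end)
        if lo < hi:
            clipped.append((lo, hi))
            by_class.setdefault(cls, []).append((lo, hi))
    masked = sum(hi - lo for lo, hi in merge_intervals(clipped))
    return RepeatOccupancy(
        intron_id=f"{i.gene_id}:{i.ordinal}",
        intron_length=iv.length,
        masked_nt=masked,
        masked_fraction=masked / iv.length,
        repeat_classes={
            cls: sum(hi - lo for lo, hi in merge_intervals(ivs))
            for cls, ivs in by_class.items()
        },
    )


def read_repeat_annotations(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read repeat intervals from BED (>=4 columns) or RepeatMasker .out.

    The format is auto-detected: RepeatMasker output starts with its
    two-line "SW perc ..." header or has whitespace-delimited records
    whose first field is a numeric Smith-Waterman score.  Intervals are
    normalized to 0-based half-open coordinates (RepeatMasker prints
    1-based closed).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    body = [l for l in lines if l.strip()]
    if not body:
        return []
    if _looks_like_rmout(body):
        return _parse_rmout(body, path)
    return _parse_bed(body, path)


def _looks_like_rmout(body: list[str]) -> bool:
    head = body[0].split()
    if head[:2] == ["SW", "perc"]:
        return True
    fields = body[0].split()
    # no tabs, >= 11 whitespace fields, numeric score column
    return ("\t" not in body[0] and len(fields) >= 11
            and fields[0].replace(".", "").isdigit()
            and fields[5].isdigit() and fields[6].isdigit())


def _parse_rmout(body: list[str], path: Path) -> list[tuple[GenomicInterval, str]]:
    out = []
    for lineno, line in enumerate(body, 1):
        fields = line.split()
        if fields[:2] == ["SW", "perc"] or fields[:1] == ["score"]:
            continue  # header lines
        if len(fields) < 11:
            raise ValueError(f"{path}:{lineno}: unrecognized RepeatMasker "
                             f"line: {line!r}")
        try:
            chrom = fields[4]
            start, end = int(fields[5]) - 1, int(fields[6])
            strand = "-" if fields[8] == "C" else "+"
            repeat_class = fields[10]
        except (ValueError, IndexError) as exc:
            raise ValueError(
                f"{path}:{lineno}: unrecognized RepeatMasker line: {line!r}"
            ) from exc
        out.append((GenomicInterval(chrom, start, end, strand), repeat_class))
    return out


def _parse_bed(body: list[str], path: Path) -> list[tuple[GenomicInterval, str]]:
    out = []
    for lineno, line in enumerate(body, 1):
        if line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: unrecognized BED line: {line!r}")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{lineno}: unrecognized BED line: {line!r}"
            ) from exc
        if end <= start:
            raise ValueError(f"{path}:{lineno}: negative-width interval")
        name = fields[3] if len(fields) > 3 else "repeat"
        strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
        out.append((GenomicInterval(chrom, start, end, strand), name))
    return out
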