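"""Shared builders for toy gene structures and trees."""

from __future__ import annotations

import numpy as np
import pytest

from introgain.gene_models import GenomicInterval, TranscriptModel
from introgain.timing import SpeciesTree

FIVE_LEAF_NEWICK = "((A:1,B:1)AB:1,(C:2,(D:1,E:1)DE:1)CDE:1)root;"


@pytest.fixture
def five_leaf_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(FIVE_LEAF_NEWICK, is_path=False)


def make_transcript(exon_bounds, cds_bounds=(), strand="+", gene_id="g",
                    species_id="sp", chrom="chr1") -> TranscriptModel:
    """Build a transcript from genomic (start, end) pairs.

    Pairs are given in ascending genomic order; for minus-strand
    transcripts they are reversed into transcription order here.
    """
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds]
    cds = [GenomicInterval(chrom, s, e, strand) for s, e in cds_bounds]
    if strand == "-":
        exons = exons[::-1]
        cds = cds[::-1]
    return TranscriptModel(gene_id=gene_id, species_id=species_id,
                           exons=exons, cds=cds, strand=strand)


def random_transcript(rng: np.random.Generator, strand=None) -> TranscriptModel:
    """Random multi-exon transcript with a CDS covering a middle stretch."""
    n_exons = int(rng.integers(2, 7))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    pos = int(rng.integers(0, 50))
    exon_bounds = []
    for _ in range(n_exons):
        length = int(rng.integers(20, 120))
        exon_bounds.append((pos, pos + length))
        pos += length + int(rng.integers(10, 400))
    # choose a CDS window in transcript coordinates, then map to genomic
    total = sum(e - s for s, e in exon_bounds)
    lo = int(rng.integers(0, total - 3))
    hi = int(rng.integers(lo + 3, total + 1))
    cds_bounds = _tx_window_to_genomic(exon_bounds, strand, lo, hi)
    return make_transcript(exon_bounds, cds_bounds, strand=strand)


def _tx_window_to_genomic(exon_bounds, strand, lo, hi):
    """Map a transcript-coordinate window onto genomic sub-intervals."""
    ordered = exon_bounds if strand == "+" else exon_bounds[::-1]
    out = []
    tx = 0
    for s, e in ordered:
        length = e - s
        a, b = max(lo, tx), min(hi, tx + length)
        if a < b:
            if strand == "+":
                out.append((s + (a - tx), s + (b - tx)))
            else:
                out.append((e - (b - tx), e - (a - tx)))
        tx += length
    return sorted(out)


# --- independent brute-force oracle (per-nucleotide codon walk) ------------

def classify_oracle(t: TranscriptModel, intron_interval) -> tuple[str, int]:
    """(region, phase) by counting coding nucleotides on each side."""
    coding = set()
    for c in t.cds:
        coding.update(range(c.start, c.end))
    five, three = 0, 0
    for e in t.exons:
        for g in (range(e.start, e.end) if t.strand == "+"
                  else range(e.end - 1, e.start - 1, -1)):
            before = (g < intron_interval.start if t.strand == "+"
                      else g >= intron_interval.end)
            if g in coding:
                if before:
                    five += 1
                else:
                    three += 1
    if not coding:
        return "noncoding", -1
    if five and three:
        return "CDS", five % 3
    return ("UTR5", -1) if five == 0 else ("UTR3", -1)
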