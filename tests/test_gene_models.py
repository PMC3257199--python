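"""Gene structure I/O, intron extraction, classification, phase, densities."""

import warnings

import numpy as np
import pytest

from introgain.gene_models import (GeneStructureError, GenomicInterval,
                                   classify_intron, cds_phase, extract_introns,
                                   gene_set_density, read_gene_structures,
                                   write_bed12, write_gff3)
from conftest import (classify_oracle, make_transcript, random_transcript)

TOY_GFF3 = """##gff-version 3
chr1\ttoy\tgene\t101\t600\t.\t+\t.\tID=geneA
chr1\ttoy\tmRNA\t101\t600\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttoy\texon\t101\t200\t.\t+\t.\tParent=geneA.t1
chr1\ttoy\texon\t301\t400\t.\t+\t.\tParent=geneA.t1
chr1\ttoy\texon\t501\t600\t.\t+\t.\tParent=geneA.t1
chr1\ttoy\tCDS\t351\t400\t.\t+\t0\tParent=geneA.t1
chr1\ttoy\tCDS\t501\t560\t.\t+\t0\tParent=geneA.t1
"""

SINGLE_EXON_GFF3 = """##gff-version 3
chr2\ttoy\tgene\t11\t110\t.\t+\t.\tID=geneB
chr2\ttoy\tmRNA\t11\t110\t.\t+\t.\tID=geneB.t1;Parent=geneB
chr2\ttoy\texon\t11\t110\t.\t+\t.\tParent=geneB.t1
"""


def zcchc16_like():
    """Human ZCCHC16-style gene: 3 exons, CDS confined to the last exon,
    5'UTR introns of 47.8 kb and 323.3 kb."""
    return make_transcript(
        [(0, 100), (47900, 48000), (371300, 371500)],
        cds_bounds=[(371350, 371449)],
        gene_id="ZCCHC16_like",
    )


class TestReadGeneStructures:
    def test_three_exon_gff3_hand_converted(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(TOY_GFF3)
        (model,) = read_gene_structures(path, "human")
        assert [(e.start, e.end) for e in model.exons] == [
            (100, 200), (300, 400), (500, 600)]
        assert [(c.start, c.end) for c in model.cds] == [
            (350, 400), (500, 560)]

    def test_single_exon_no_cds(self, tmp_path):
        path = tmp_path / "single.gff3"
        path.write_text(SINGLE_EXON_GFF3)
        (model,) = read_gene_structures(path, "human")
        assert len(model.exons) == 1 and model.cds == []
        assert extract_introns(model) == []

    def test_minus_strand_exons_in_transcription_order(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\ttoy\tgene\t101\t400\t.\t-\t.\tID=gm\n"
            "chr1\ttoy\tmRNA\t101\t400\t.\t-\t.\tID=gm.t1;Parent=gm\n"
            "chr1\ttoy\texon\t101\t150\t.\t-\t.\tParent=gm.t1\n"
            "chr1\ttoy\texon\t301\t400\t.\t-\t.\tParent=gm.t1\n"
        )
        path = tmp_path / "minus.gff3"
        path.write_text(gff)
        (model,) = read_gene_structures(path, "mouse")
        # first exon in transcription order is the genomically last one
        assert (model.exons[0].start, model.exons[0].end) == (300, 400)

    def test_cds_outside_exons_rejected(self, tmp_path):
        bad = TOY_GFF3 + "chr1\ttoy\tCDS\t251\t260\t.\t+\t0\tParent=geneA.t1\n"
        path = tmp_path / "bad.gff3"
        path.write_text(bad)
        with pytest.raises(GeneStructureError, match="geneA"):
            read_gene_structures(path, "human")

    def test_bed12_blocks_and_thick_range(self, tmp_path):
        bed = "chr1\t100\t600\tgeneA\t0\t+\t350\t560\t0\t3\t100,100,100\t0,200,400\n"
        path = tmp_path / "toy.bed"
        path.write_text(bed)
        (model,) = read_gene_structures(path, "human")
        assert [(e.start, e.end) for e in model.exons] == [
            (100, 200), (300, 400), (500, 600)]
        assert [(c.start, c.end) for c in model.cds] == [
            (350, 400), (500, 560)]


class TestExtractClassify:
    def test_zcchc16_like_two_long_utr5_introns(self):
        introns = extract_introns(zcchc16_like())
        assert [i.length for i in introns] == [47800, 323300]
        assert {i.region_class for i in introns} == {"UTR5"}

    def test_intron_between_coding_exons_is_cds(self):
        t = make_transcript([(0, 99), (200, 299)], [(0, 99), (200, 299)])
        (intron,) = extract_introns(t)
        assert classify_intron(t, intron) == "CDS"
        assert cds_phase(t, intron) == 99 % 3

    def test_start_codon_straddling_introns_mixed_labels(self):
        # NYNRIN-style: introns on both sides of the start codon
        t = make_transcript(
            [(0, 50), (100, 150), (200, 260)],
            cds_bounds=[(120, 150), (200, 260)],
        )
        introns = extract_introns(t)
        assert [i.region_class for i in introns] == ["UTR5", "CDS"]

    def test_cds_phase_examples(self):
        # intron after exactly one codon -> phase 0
        t0 = make_transcript([(0, 3), (100, 160)], [(0, 3), (100, 160)])
        assert cds_phase(t0, extract_introns(t0)[0]) == 0
        # intron after 4 coding nt -> phase 1
        t1 = make_transcript([(0, 4), (100, 160)], [(0, 4), (100, 160)])
        assert cds_phase(t1, extract_introns(t1)[0]) == 1

    def test_no_cds_yields_noncoding_marker_with_warning(self):
        t = make_transcript([(0, 50), (100, 150)])
        with pytest.warns(UserWarning, match="noncoding"):
            introns = extract_introns(t)
        assert introns[0].region_class == "noncoding"

    def test_short_gap_dropped_with_warning(self):
        t = make_transcript([(0, 50), (52, 100), (200, 250)])
        with pytest.warns(UserWarning, match="exon gap"):
            introns = extract_introns(t)
        assert len(introns) == 1 and introns[0].length == 100

    @pytest.mark.parametrize("seed", range(8))
    def test_random_transcripts_match_bruteforce_oracle(self, seed):
        """Intron set, class and phase equal a per-nucleotide codon walk."""
        rng = np.random.default_rng(seed)
        for _ in range(25):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = random_transcript(rng)
                introns = extract_introns(t)
            # brute-force gap scan over sorted exon boundaries
            genomic = sorted(t.exons, key=lambda e: e.start)
            gaps = [(a.end, b.start) for a, b in zip(genomic, genomic[1:])
                    if b.start - a.end >= 4]
            assert sorted((i.interval.start, i.interval.end)
                          for i in introns) == gaps
            assert len(introns) <= len(t.exons) - 1
            for intron in introns:
                region, phase = classify_oracle(t, intron.interval)
                assert intron.region_class == region
                if region == "CDS":
                    assert intron.phase == phase

    @pytest.mark.parametrize("seed", range(4))
    def test_span_identity_and_partition(self, seed):
        rng = np.random.default_rng(100 + seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = random_transcript(rng)
            introns = extract_introns(t)
        span = t.span
        short_gaps = (len(t.exons) - 1) - len(introns)
        if short_gaps == 0:
            assert (sum(i.length for i in introns) + t.exon_length
                    == span.length)
        counts = sum(1 for i in introns
                     if i.region_class in ("UTR5", "CDS", "UTR3", "noncoding"))
        assert counts == len(introns)


class TestDensity:
    def test_single_gene_one_intron_per_kb(self):
        t = make_transcript([(0, 500), (600, 1100)], [(0, 500), (600, 1100)])
        d = gene_set_density([t])
        assert d.density_cds == pytest.approx(1.0)

    def test_pooled_density_is_total_over_total(self):
        # 2 introns / 500 nt CDS and 0 introns / 1500 nt CDS -> (2+0)/2 kb
        g1 = make_transcript([(0, 100), (200, 400), (500, 700)],
                             [(0, 100), (200, 400), (500, 700)],
                             gene_id="g1")
        g2 = make_transcript([(0, 1500)], [(0, 1500)], gene_id="g2")
        d = gene_set_density([g1, g2])
        assert d.n_introns_cds == 2
        assert d.kb_cds == pytest.approx(2.0)
        assert d.density_cds == pytest.approx(1.0)

    def test_empty_gene_list_all_zero(self):
        d = gene_set_density([])
        assert (d.n_introns_cds, d.n_introns_utr5) == (0, 0)
        assert d.density_cds == 0.0 and d.density_utr5 == 0.0

    def test_density_invariant_under_reordering_and_splitting(self):
        rng = np.random.default_rng(7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            genes = [random_transcript(rng) for _ in range(6)]
            base = gene_set_density(genes)
            perm = gene_set_density(genes[::-1])
            half_a = gene_set_density(genes[:3])
            half_b = gene_set_density(genes[3:])
        assert perm.density_cds == pytest.approx(base.density_cds)
        # pooled recomputation from raw totals of the two halves
        n = half_a.n_introns_cds + half_b.n_introns_cds
        kb = half_a.kb_cds + half_b.kb_cds
        if kb > 0:
            assert n / kb == pytest.approx(base.density_cds)


class TestRoundTrip:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_gff3_write_read_identity(self, tmp_path, strand):
        t = make_transcript([(100, 200), (300, 400), (500, 640)],
                            [(350, 400), (500, 560)], strand=strand)
        path = tmp_path / "rt.gff3"
        write_gff3([t], path)
        (back,) = read_gene_structures(path, t.species_id)
        assert back.exons == t.exons
        assert back.cds == t.cds
        assert back.strand == t.strand
        # idempotence: a second write/read cycle is stable
        path2 = tmp_path / "rt2.gff3"
        write_gff3([back], path2)
        (back2,) = read_gene_structures(path2, t.species_id)
        assert back2.exons == back.exons and back2.cds == back.cds

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_bed12_write_read_identity(self, tmp_path, strand):
        t = make_transcript([(100, 200), (300, 400), (500, 640)],
                            [(350, 400), (500, 560)], strand=strand)
        path = tmp_path / "rt.bed"
        write_bed12([t], path)
        (back,) = read_gene_structures(path, t.species_id)
        assert back.exons == t.exons
        assert back.cds == t.cds


def test_interval_invariants():
    with pytest.raises(GeneStructureError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(GeneStructureError):
        GenomicInterval("chr1", 5, 10, strand="*")
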