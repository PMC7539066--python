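import pytest

from splicescape.models import GeneModel, GenomeSequence, TranscriptModel, reverse_complement
from splicescape.ptc import (
    classify_ptc,
    expression_filter,
    genomic_to_tx,
    ptc_census,
    reference_orf,
    tx_to_genomic,
    write_ptc_table,
    PTCCall,
)

from conftest import expr_matrix, make_gene, make_tx

SENSE8 = "CAC" * 8

# Hand-built two-exon gene: exon1 (1-30) carries the start codon at
# genomic 4-6, exon2 carries 7 coding codons, the reference stop TAA at
# genomic (62+21)=83-85, and a 6-nt 3' UTR.
EXON1 = "AAA" + "ATG" + SENSE8  # 30 nt
EXON2 = "CCT" + "AAC" + "CCC" * 5 + "TAA" + "AAAAAA"  # 30 nt


def _two_exon_case(intron_seq):
    """Gene whose t1 splices the intron and t2 retains it; returns
    (genome, gene, retained_intron, ref_stop_first_base)."""
    n_i = len(intron_seq)
    chrom = EXON1 + intron_seq + EXON2
    e2_start = 31 + n_i
    t1 = make_tx("G.t1", [(1, 30), (e2_start, e2_start + 29)], gid="G",
                 cds=(4, e2_start + 23))  # CDS includes the stop codon
    t2 = make_tx("G.t2", [(1, 30 + n_i + 30)], gid="G")
    gene = make_gene([t1, t2], gid="G")
    genome = GenomeSequence({"chr1": chrom})
    return genome, gene, (31, 30 + n_i), e2_start + 21


def _mirror(genome, gene, intron):
    """Reverse-complement the chromosome and flip all coordinates, so the
    same biology sits on the minus strand."""
    L = genome.length("chr1")
    flipped = GenomeSequence({"chr1": reverse_complement(genome.sequence("chr1"))})

    def flip_iv(iv):
        return (L - iv[1] + 1, L - iv[0] + 1)

    new_txs = []
    for t in gene.transcripts:
        exons = tuple(sorted(flip_iv(e) for e in t.exons))
        cds = flip_iv(t.cds) if t.cds else None
        new_txs.append(
            TranscriptModel(t.transcript_id, t.gene_id, t.chrom, "-", exons, cds=cds)
        )
    return flipped, GeneModel(gene.gene_id, gene.chrom, "-", new_txs), flip_iv(intron)


class TestCoordinateMaps:
    def test_tx_to_genomic_round_trip_both_strands(self):
        for strand in "+-":
            t = make_tx("t", [(11, 20), (31, 40)], strand=strand)
            for pos in range(t.spliced_length):
                g = tx_to_genomic(t, pos)
                assert genomic_to_tx(t, g) == pos

    def test_intronic_position_maps_to_none(self):
        t = make_tx("t", [(11, 20), (31, 40)])
        assert genomic_to_tx(t, 25) is None

    def test_out_of_range_rejected(self):
        t = make_tx("t", [(11, 20)])
        with pytest.raises(ValueError):
            tx_to_genomic(t, 10)


class TestReferenceORF:
    def test_annotated_cds_wins(self):
        genome, gene, _, ref_stop = _two_exon_case("GT" + "C" * 26 + "AG")
        ref = reference_orf(gene, genome)
        assert ref.transcript_id == "G.t1"
        assert ref.start == 4
        assert ref.stop == ref_stop

    def test_fallback_longest_orf(self):
        seq = "AAAA" + "ATG" + "CAC" * 120 + "TAA" + "CC"
        genome = GenomeSequence({"chr1": seq})
        gene = make_gene([make_tx("G.t1", [(1, len(seq))], gid="G")], gid="G")
        ref = reference_orf(gene, genome)
        assert ref.start == 5
        assert ref.stop == 5 + 3 + 360

    def test_short_orf_gives_none(self):
        seq = "AAAA" + "ATG" + "CAC" * 10 + "TAA" + "CC"
        genome = GenomeSequence({"chr1": seq})
        gene = make_gene([make_tx("G.t1", [(1, len(seq))], gid="G")], gid="G")
        assert reference_orf(gene, genome) is None


class TestClassifyPTC:
    def test_inframe_stop_free_intron_is_ptc_minus(self):
        # 30-nt (3n) stop-free retained intron: frame preserved, the first
        # stop is the reference stop itself
        genome, gene, intron, _ = _two_exon_case("GT" + "C" * 26 + "AG")
        call = classify_ptc(gene.transcripts[1], reference_orf(gene, genome), genome, intron)
        assert call.status == "PTC-"

    def test_stop_containing_intron_is_ptc_plus(self):
        # in-frame TAA inside the retained intron
        genome, gene, intron, _ = _two_exon_case("GTC" + "TAA" + "CCC" * 7 + "CAG")
        call = classify_ptc(gene.transcripts[1], reference_orf(gene, genome), genome, intron)
        assert call.status == "PTC+"
        assert call.first_stop_tx == 33  # intron offset 3, after 10 codons

    def test_frameshifting_intron_is_ptc_plus(self):
        # 31-nt stop-free intron shifts the frame; the shifted reading of
        # the downstream exon hits TAA at genomic 64+len diff
        genome, gene, intron, ref_stop = _two_exon_case("GT" + "C" * 27 + "AG")
        call = classify_ptc(gene.transcripts[1], reference_orf(gene, genome), genome, intron)
        assert call.status == "PTC+"
        stop_g = tx_to_genomic(gene.transcripts[1], call.first_stop_tx)
        assert stop_g < ref_stop

    def test_utr_intron_is_ptc_minus(self):
        # the retained intron sits in the 3' UTR, downstream of the stop
        exon1 = "AAA" + "ATG" + "CAC" * 16 + "TAA"  # 57 nt, CDS 4-57
        intron = "GT" + "C" * 26 + "AG"
        exon2 = "A" * 30
        chrom = exon1 + intron + exon2
        t1 = make_tx("G.t1", [(1, 57), (88, 117)], gid="G", cds=(4, 57))
        t2 = make_tx("G.t2", [(1, 117)], gid="G")
        gene = make_gene([t1, t2], gid="G")
        genome = GenomeSequence({"chr1": chrom})
        call = classify_ptc(t2, reference_orf(gene, genome), genome, (58, 87))
        assert call.status == "PTC-"

    def test_strand_mirror_invariance(self):
        for intron_seq in ("GT" + "C" * 26 + "AG",  # PTC-
                           "GTC" + "TAA" + "CCC" * 7 + "CAG",  # PTC+
                           "GT" + "C" * 27 + "AG"):  # frameshift PTC+
            genome, gene, intron, _ = _two_exon_case(intron_seq)
            fwd = classify_ptc(
                gene.transcripts[1], reference_orf(gene, genome), genome, intron
            )
            mgenome, mgene, mintron = _mirror(genome, gene, intron)
            rev = classify_ptc(
                mgene.transcripts[1], reference_orf(mgene, mgenome), mgenome, mintron
            )
            assert fwd.status == rev.status

    def test_missing_reference_is_undetermined(self):
        genome, gene, intron, _ = _two_exon_case("GT" + "C" * 26 + "AG")
        call = classify_ptc(gene.transcripts[1], None, genome, intron)
        assert call.status == "undetermined"

    def test_intron_not_retained_rejected(self):
        genome, gene, intron, _ = _two_exon_case("GT" + "C" * 26 + "AG")
        with pytest.raises(ValueError, match="does not retain"):
            classify_ptc(gene.transcripts[0], reference_orf(gene, genome), genome, intron)

    def test_nmd_flag_set_when_stop_far_from_last_junction(self):
        # three-exon retaining isoform: premature stop in the retained
        # first intron, > 50 nt upstream of the remaining junction
        exon1 = "AAA" + "ATG" + SENSE8  # 30 nt, start at 4
        intron1 = "GTC" + "TAA" + "CCC" * 7 + "CAG"  # 30 nt, in-frame stop
        exon2 = "CAC" * 10  # 30 nt
        intron2 = "GT" + "C" * 56 + "AG"  # 60 nt
        exon3 = "CAC" * 30 + "TAA" + "A" * 7  # 100 nt
        chrom = exon1 + intron1 + exon2 + intron2 + exon3
        t1 = make_tx("G.t1", [(1, 30), (61, 90), (151, 250)], gid="G", cds=(4, 243))
        t2 = make_tx("G.t2", [(1, 90), (151, 250)], gid="G")
        gene = make_gene([t1, t2], gid="G")
        genome = GenomeSequence({"chr1": chrom})
        call = classify_ptc(t2, reference_orf(gene, genome), genome, (31, 60))
        assert call.status == "PTC+"
        assert call.nmd_50nt_flag


class TestExpressionFilter:
    def test_keeps_only_expressed(self):
        expr = expr_matrix(
            {
                "t_on": {"leaf": 2.0},
                "t_border": {"petal": 1.0},
                "t_off": {"leaf": 0.4, "petal": 0.9},
            }
        )
        kept = expression_filter(["t_on", "t_border", "t_off"], expr)
        assert kept == ["t_on", "t_border"]

    def test_threshold_respected(self):
        expr = expr_matrix({"t": {"leaf": 3.0}})
        assert expression_filter(["t"], expr, min_fpkm=5.0) == []

    def test_missing_transcript_named_in_error(self):
        expr = expr_matrix({"t": {"leaf": 3.0}})
        with pytest.raises(ValueError, match="ghost"):
            expression_filter(["ghost"], expr)


class TestCensusAndTable:
    def _calls(self):
        return [
            PTCCall("t1", "G1", (1, 10), "PTC+"),
            PTCCall("t2", "G1", (1, 10), "PTC-"),
            PTCCall("t3", "G2", (5, 20), "PTC-"),
            PTCCall("t4", "G2", (5, 20), "undetermined"),
        ]

    def test_census_tallies(self):
        expr = expr_matrix(
            {
                "t1": {"leaf": 5.0, "petal": 5.0},  # shared
                "t2": {"leaf": 5.0},  # leaf-specific
                "t3": {},  # absent everywhere
                "t4": {"leaf": 5.0, "petal": 5.0},
            }
        )
        census = ptc_census(self._calls(), expr)
        assert census.n_plus == 1 and census.n_minus == 1  # t3 absent, t4 unresolved
        assert census.shared == {"PTC+": 1, "PTC-": 0}
        assert census.specific["leaf"] == {"PTC+": 0, "PTC-": 1}
        assert census.ratio == 1.0

    def test_ratio_none_when_no_minus(self):
        expr = expr_matrix({"t1": {"leaf": 5.0}})
        census = ptc_census([PTCCall("t1", "G1", (1, 10), "PTC+")], expr)
        assert census.ratio is None

    def test_table_export(self, tmp_path):
        p = tmp_path / "ptc.tsv"
        write_ptc_table(self._calls(), str(p))
        lines = p.read_text().strip().split("\n")
        assert len(lines) == 5
        assert lines[1].split("\t") == ["t1", "G1", "1", "10", "PTC+", "0"]
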