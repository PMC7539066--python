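import numpy as np
import pytest

from _oracles import brute_force_events, package_events_as_calls, random_gene_model
from splicescape.events import (
    EVENT_TYPES,
    classify_genes,
    enumerate_all,
    enumerate_events,
    event_summary,
    tissue_specific_sets,
    write_event_table,
)

from conftest import expr_matrix, make_gene, make_tx


def only_event(gene):
    events = enumerate_events(gene)
    assert len(events) == 1, [e.event_id for e in events]
    return events[0]


class TestEventDefinitions:
    def test_ir(self, ir_gene):
        ev = only_event(ir_gene)
        assert ev.event_type == "IR"
        assert ev.signature == (400, 501)  # ends of the flanking exons
        assert ev.inclusion == {"G1.t2"}  # the retaining isoform
        assert ev.exclusion == {"G1.t1"}

    def test_es(self, es_gene):
        ev = only_event(es_gene)
        assert ev.event_type == "ES"
        assert ev.signature == (200, 301, 400, 501)
        assert ev.inclusion == {"G2.t1"}
        assert ev.exclusion == {"G2.t2"}

    def test_a5_plus_strand(self):
        # t2 moves the donor of the first intron 20 nt inward (longer intron)
        t1 = make_tx("G.t1", [(101, 200), (301, 400)], gid="G")
        t2 = make_tx("G.t2", [(101, 180), (301, 400)], gid="G")
        ev = only_event(make_gene([t1, t2], gid="G"))
        assert ev.event_type == "A5"
        assert ev.signature == (181, 201, 300)
        assert ev.inclusion == {"G.t1"}  # shorter intron keeps more exon
        assert ev.exclusion == {"G.t2"}

    def test_a3_plus_strand(self):
        t1 = make_tx("G.t1", [(101, 200), (301, 400)], gid="G")
        t2 = make_tx("G.t2", [(101, 200), (321, 400)], gid="G")
        ev = only_event(make_gene([t1, t2], gid="G"))
        assert ev.event_type == "A3"
        assert ev.inclusion == {"G.t1"}

    def test_a5_a3_swap_on_minus_strand(self):
        # same coordinates as the A5 case above but on '-': the differing
        # genomic-left boundary is now the acceptor side
        t1 = make_tx("G.t1", [(101, 200), (301, 400)], gid="G", strand="-")
        t2 = make_tx("G.t2", [(101, 180), (301, 400)], gid="G", strand="-")
        ev = only_event(make_gene([t1, t2], gid="G", strand="-"))
        assert ev.event_type == "A3"

    def test_mx(self):
        t1 = make_tx("G.t1", [(101, 200), (301, 350), (601, 700)], gid="G")
        t2 = make_tx("G.t2", [(101, 200), (401, 450), (601, 700)], gid="G")
        ev = only_event(make_gene([t1, t2], gid="G"))
        assert ev.event_type == "MX"
        assert ev.signature == (301, 350, 401, 450)
        assert ev.inclusion == {"G.t1"}  # 5'-most internal exon on '+'

    def test_af(self):
        t1 = make_tx("G.t1", [(101, 150), (301, 400)], gid="G")
        t2 = make_tx("G.t2", [(181, 230), (301, 400)], gid="G")
        ev = only_event(make_gene([t1, t2], gid="G"))
        assert ev.event_type == "AF"
        assert ev.inclusion == {"G.t1"}

    def test_al(self):
        t1 = make_tx("G.t1", [(101, 200), (301, 350)], gid="G")
        t2 = make_tx("G.t2", [(101, 200), (401, 460)], gid="G")
        ev = only_event(make_gene([t1, t2], gid="G"))
        assert ev.event_type == "AL"
        # 5'-most terminal exon on '+' is the genomically left one
        assert ev.inclusion == {"G.t1"}

    def test_overlapping_terminal_exons_are_a5_not_af(self):
        # first exons overlap and the adjacent introns share the acceptor:
        # this is an alternative donor, not an alternative first exon
        t1 = make_tx("G.t1", [(101, 200), (301, 400)], gid="G")
        t2 = make_tx("G.t2", [(121, 180), (301, 400)], gid="G")
        ev = only_event(make_gene([t1, t2], gid="G"))
        assert ev.event_type == "A5"

    def test_single_transcript_gene_yields_nothing(self):
        g = make_gene([make_tx("G.t1", [(101, 200), (301, 400)])])
        assert enumerate_events(g) == []

    def test_identical_isoforms_yield_nothing(self):
        t1 = make_tx("G.t1", [(101, 200), (301, 400)], gid="G")
        t2 = make_tx("G.t2", [(101, 200), (301, 400)], gid="G")
        assert enumerate_events(make_gene([t1, t2], gid="G")) == []

    def test_single_exon_partner_gives_ir(self):
        # a single-exon isoform spanning both exons retains the intron
        t1 = make_tx("G.t1", [(101, 200), (301, 400)], gid="G")
        t2 = make_tx("G.t2", [(101, 400)], gid="G")
        ev = only_event(make_gene([t1, t2], gid="G"))
        assert ev.event_type == "IR"
        assert ev.inclusion == {"G.t2"}


class TestDeduplication:
    def test_shared_event_unions_transcript_sets(self):
        # three isoforms: t1/t2 both splice the intron, t3 retains it
        t1 = make_tx("G.t1", [(101, 200), (301, 400), (501, 600)], gid="G")
        t2 = make_tx("G.t2", [(301, 400), (501, 600)], gid="G")
        t3 = make_tx("G.t3", [(101, 200), (301, 600)], gid="G")
        events = enumerate_events(make_gene([t1, t2, t3], gid="G"))
        ir = [e for e in events if e.event_type == "IR"]
        assert len(ir) == 1
        assert ir[0].inclusion == {"G.t3"}
        assert ir[0].exclusion == {"G.t1", "G.t2"}

    def test_event_id_is_stable(self, ir_gene):
        ev = enumerate_events(ir_gene)[0]
        assert ev.event_id == "G1:IR:400-501"

    def test_oracle_equivalence_random_sample(self, rng):
        for i in range(300):
            g = random_gene_model(rng, f"R{i:04d}")
            assert package_events_as_calls(enumerate_events(g)) == brute_force_events(g)


class TestClassifyGenes:
    def test_counts_and_percent(self, ir_gene, es_gene):
        solo = make_gene([make_tx("G3.t1", [(1, 50)], gid="G3")], gid="G3")
        genes = [ir_gene, es_gene, solo, _renamed_solo("G4")]
        events = enumerate_all(genes)
        flags, pct = classify_genes(genes, events)
        assert flags == {"G1": True, "G2": True, "G3": False, "G4": False}
        assert pct == 50.0

    def test_unknown_gene_rejected(self, ir_gene):
        events = enumerate_events(ir_gene)
        with pytest.raises(ValueError, match="unknown gene"):
            classify_genes([], events)

    def test_empty_inputs(self):
        assert classify_genes([], []) == ({}, 0.0)


def _renamed_solo(gid):
    return make_gene([make_tx(f"{gid}.t1", [(1, 50)], gid=gid)], gid=gid)


class TestEventSummary:
    def test_counts_mode_matches_manual_arithmetic(self):
        counts = {"IR": 3, "ES": 1, "A3": 0, "A5": 0, "AF": 0, "AL": 0, "MX": 0}
        summ = event_summary(counts)
        assert summ.total == 4
        assert summ.proportions["IR"] == 75.0
        assert summ.proportions["ES"] == 25.0

    def test_proportions_sum_to_100(self, rng):
        for _ in range(100):
            counts = {t: int(rng.integers(0, 50)) for t in EVENT_TYPES}
            if sum(counts.values()) == 0:
                continue
            summ = event_summary(counts)
            assert abs(sum(summ.proportions.values()) - 100.0) <= 0.05

    def test_empty_is_flagged(self):
        summ = event_summary([])
        assert summ.empty and summ.total == 0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            event_summary({"IR": -1})

    def test_event_objects_mode(self, ir_gene, es_gene):
        summ = event_summary(enumerate_all([ir_gene, es_gene]))
        assert summ.counts["IR"] == 1 and summ.counts["ES"] == 1
        assert summ.total == 2


class TestTissueSpecificity:
    def test_transcript_and_gene_specificity(self, ir_gene):
        events = enumerate_events(ir_gene)
        expr = expr_matrix(
            {
                "G1.t1": {"leaf": 5.0, "petal": 5.0},  # ubiquitous
                "G1.t2": {"leaf": 4.0},  # leaf-specific
            }
        )
        out = tissue_specific_sets(events, [ir_gene], expr)
        assert out["transcripts"]["leaf"] == {"G1.t2"}
        assert out["transcripts"]["petal"] == set()
        # the gene is present wherever any isoform is -> not specific
        assert out["genes"]["leaf"] == set()

    def test_missing_expression_row_rejected(self, ir_gene):
        events = enumerate_events(ir_gene)
        expr = expr_matrix({"G1.t1": {"leaf": 5.0}})
        with pytest.raises(ValueError, match="no expression rows"):
            tissue_specific_sets(events, [ir_gene], expr)


class TestEventTable:
    def test_tsv_round_trip_fields(self, tmp_path, ir_gene):
        events = enumerate_events(ir_gene)
        p = tmp_path / "events.tsv"
        write_event_table(events, str(p))
        lines = p.read_text().strip().split("\n")
        assert lines[0].split("\t")[0] == "gene_id"
        row = lines[1].split("\t")
        assert row[:4] == ["G1", "G1:IR:400-501", "IR", "400-501"]
        assert row[4] == "G1.t2" and row[5] == "G1.t1"
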