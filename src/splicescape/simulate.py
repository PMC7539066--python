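"""Synthetic multi-isoform transcriptome generator with planted truth.

The generator emulates the study design the analysis modules target: a
multi-exon gene catalog in which a configurable fraction of genes carry
exactly one planted alternative-splicing event (type mix defaulting to
the observed plant-transcriptome proportions, intron retention first), a
genome whose intron-terminal dinucleotides follow a planted canonical
GT-AG fraction, retained-intron isoforms engineered to be PTC+ or PTC-
at a planted ratio, and a 7-tissue x 3-replicate FPKM design with
planted coexpression modules, hub genes, and tissue-specific
transcripts. Everything is keyed to a seed and emitted alongside truth
tables, so downstream modules can be tested as exact parameter-recovery
experiments.

Event-type counts, the PTC+ share, and the canonical-site share are
allocated by largest-remainder rounding rather than sampled, so realized
proportions equal configured proportions exactly whenever the quota is
integral and to within one count otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .events import ASEvent
from .models import GeneModel, GenomeSequence, TranscriptModel, introns_of, reverse_complement
from .ptc import genomic_to_tx, tx_to_genomic

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_annotation", "simulate_expression", "simulate_bundle"]

DEFAULT_EVENT_PROPORTIONS = {
    "IR": 0.2839,
    "A3": 0.2029,
    "ES": 0.1668,
    "A5": 0.1527,
    "AF": 0.1166,
    "AL": 0.0634,
    "MX": 0.0137,
}

DEFAULT_TISSUES = ("leaf", "shoot_apex", "sepal", "bract", "petal", "pistil", "stamen")

NONCANONICAL_SITES = (("GC", "AG"), ("AT", "AC"), ("AA", "AG"), ("GT", "TG"), ("GT", "TT"))

STOPS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the study conditions."""

    seed: int = 0
    n_genes: int = 500
    fraction_as: float = 0.1756
    event_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_PROPORTIONS)
    )
    canonical_fraction: float = 0.90
    ptc_plus_fraction: float = 1.0 / 3.0  # PTC+ : PTC- of one to two
    tissues: Tuple[str, ...] = DEFAULT_TISSUES
    n_replicates: int = 3
    as_exon_count: Tuple[int, int] = (5, 9)
    non_as_exon_count: Tuple[int, int] = (1, 6)
    exon_length: Tuple[int, int] = (80, 300)
    intron_length: Tuple[int, int] = (150, 400)
    ir_intron_length: Tuple[int, int] = (60, 120)  # retained introns run short
    terminal_exon_margin: int = 60
    n_modules: int = 3
    module_size: int = 100
    within_module_cor: float = 0.8
    hub_cor: float = 1.0  # hub = the module eigengene itself
    replicate_noise_sd: float = 0.3
    fraction_tissue_specific: float = 0.05
    low_expression_fraction: float = 0.0
    genes_per_chromosome: int = 100
    intergenic_gap: int = 500

    def validate(self) -> None:
        total = sum(self.event_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event proportions sum to {total}, not 1")
        for name, frac in [
            ("fraction_as", self.fraction_as),
            ("canonical_fraction", self.canonical_fraction),
            ("ptc_plus_fraction", self.ptc_plus_fraction),
            ("fraction_tissue_specific", self.fraction_tissue_specific),
            ("low_expression_fraction", self.low_expression_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.event_proportions.get("MX", 0) > 0 and self.as_exon_count[1] < 3:
            raise ValueError(
                "MX events need genes with at least 3 exons; raise as_exon_count"
            )
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module sizes exceed gene count")


@dataclass
class SimulationTruth:
    """Planted ground truth keyed by the simulation seed."""

    seed: int
    events: List[ASEvent] = field(default_factory=list)
    splice_sites: List[dict] = field(default_factory=list)
    ptc_status: Dict[str, dict] = field(default_factory=dict)
    modules: Dict[str, int] = field(default_factory=dict)
    hubs: Set[str] = field(default_factory=set)
    tissue_specific: Dict[str, str] = field(default_factory=dict)
    low_expression: Set[str] = field(default_factory=set)
    as_genes: Set[str] = field(default_factory=set)

    def event_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for ev in self.events:
            out[ev.event_type] = out.get(ev.event_type, 0) + 1
        return out

    def save(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "events.tsv"), "w") as fh:
            fh.write("gene_id\tevent_type\tsignature\tinclusion\texclusion\n")
            for ev in self.events:
                sig = "-".join(map(str, ev.signature))
                fh.write(
                    f"{ev.gene_id}\t{ev.event_type}\t{sig}\t"
                    f"{','.join(sorted(ev.inclusion))}\t{','.join(sorted(ev.exclusion))}\n"
                )
        with open(os.path.join(outdir, "splice_sites.tsv"), "w") as fh:
            fh.write("gene_id\tchrom\tstart\tend\tstrand\tdonor\tacceptor\n")
            for s in self.splice_sites:
                fh.write(
                    f"{s['gene_id']}\t{s['chrom']}\t{s['start']}\t{s['end']}\t"
                    f"{s['strand']}\t{s['donor']}\t{s['acceptor']}\n"
                )
        with open(os.path.join(outdir, "ptc_status.tsv"), "w") as fh:
            fh.write("transcript_id\tgene_id\tintron_start\tintron_end\tstatus\n")
            for tid in sorted(self.ptc_status):
                p = self.ptc_status[tid]
                fh.write(
                    f"{tid}\t{p['gene_id']}\t{p['intron'][0]}\t{p['intron'][1]}\t{p['status']}\n"
                )
        with open(os.path.join(outdir, "modules.tsv"), "w") as fh:
            fh.write("gene_id\tmodule\thub\n")
            for gid in sorted(self.modules):
                fh.write(f"{gid}\t{self.modules[gid]}\t{int(gid in self.hubs)}\n")
        with open(os.path.join(outdir, "tissue_specific.tsv"), "w") as fh:
            fh.write("transcript_id\ttissue\n")
            for tid in sorted(self.tissue_specific):
                fh.write(f"{tid}\t{self.tissue_specific[tid]}\n")


def largest_remainder(total: int, proportions: Dict[str, float]) -> Dict[str, int]:
    """Integer allocation of ``total`` by the largest-remainder rule.

    Ties in the fractional remainders break toward the larger
    proportion, then lexicographically, so allocation is deterministic.
    """
    keys = sorted(proportions, key=lambda k: (-proportions[k], k))
    quotas = {k: total * proportions[k] for k in keys}
    counts = {k: int(math.floor(quotas[k])) for k in keys}
    short = total - sum(counts.values())
    by_rem = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), -proportions[k], k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


# --------------------------------------------------------------------------
# gene construction


def _gene_layout(
    rng: np.random.Generator,
    n_exons: int,
    cfg: SimulationConfig,
    etype: Optional[str],
    strand: str,
) -> Tuple[List[int], List[int], Dict[str, int]]:
    """Exon and intron lengths for one gene, leaving room for the planted
    event edit; returns (exon_lengths, intron_lengths, slots)."""
    exon_len = [int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1)) for _ in range(n_exons)]
    intron_len = [
        int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        for _ in range(max(0, n_exons - 1))
    ]
    slots: Dict[str, int] = {}
    margin = cfg.terminal_exon_margin
    if etype == "IR":
        lo, hi = cfg.ir_intron_length
        intron_len = [int(rng.integers(lo, hi + 1)) for _ in intron_len]
        k = (n_exons - 1) // 2
        # retained intron: length a multiple of 3 and >= 12 so frame and
        # stop placement are controllable
        L = max(12, intron_len[k] - intron_len[k] % 3)
        intron_len[k] = L
        slots["intron"] = k
    elif etype in ("A5", "A3"):
        slots["intron"] = (n_exons - 1) // 2
        slots["shift"] = int(rng.integers(9, 31))
    elif etype == "ES":
        slots["exon"] = n_exons // 2
    elif etype == "MX":
        k = n_exons // 2
        alt_len = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        intron_len[k] = alt_len + 2 * margin  # intron after exon k hosts the partner
        slots["exon"] = k
        slots["alt_len"] = alt_len
    elif etype in ("AF", "AL"):
        # the alternative terminal exon sits in the genomic-left intron for
        # AF on '+' / AL on '-', else in the genomic-right intron
        alt_len = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        left_end = (etype == "AF") == (strand == "+")
        intron_len[0 if left_end else -1] = alt_len + 2 * margin
        slots["alt_len"] = alt_len
    return exon_len, intron_len, slots


def _place(offset: int, exon_len: List[int], intron_len: List[int]) -> List[Tuple[int, int]]:
    exons = []
    pos = offset + 1
    for i, el in enumerate(exon_len):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_len):
            pos += intron_len[i]
    return exons


def _build_gene(
    gid: str,
    chrom: str,
    offset: int,
    strand: str,
    etype: Optional[str],
    rng: np.random.Generator,
    cfg: SimulationConfig,
) -> Tuple[GeneModel, Optional[ASEvent], Dict, int]:
    """One gene (base isoform plus the planted alternative, if any)."""
    if etype is None:
        lo, hi = cfg.non_as_exon_count
    else:
        lo, hi = cfg.as_exon_count
        lo = max(lo, 3 if etype in ("MX", "ES") else 2)
    n_exons = int(rng.integers(lo, hi + 1))
    exon_len, intron_len, slots = _gene_layout(rng, n_exons, cfg, etype, strand)
    exons = _place(offset, exon_len, intron_len)
    margin = cfg.terminal_exon_margin

    base = TranscriptModel(f"{gid}.t1", gid, chrom, strand, tuple(exons))
    transcripts = [base]
    event: Optional[ASEvent] = None
    extra: Dict = {}

    if etype is not None:
        alt_exons: List[Tuple[int, int]] = list(exons)
        if etype == "IR":
            k = slots["intron"]
            merged = (exons[k][0], exons[k + 1][1])
            alt_exons = exons[:k] + [merged] + exons[k + 2 :]
            sig = (exons[k][1], exons[k + 1][0])
            inc, exc = {f"{gid}.t2"}, {f"{gid}.t1"}
            extra["retained_intron"] = (exons[k][1] + 1, exons[k + 1][0] - 1)
        elif etype == "ES":
            k = slots["exon"]
            alt_exons = exons[:k] + exons[k + 1 :]
            sig = (exons[k - 1][1], exons[k][0], exons[k][1], exons[k + 1][0])
            inc, exc = {f"{gid}.t1"}, {f"{gid}.t2"}
        elif etype in ("A5", "A3"):
            k = slots["intron"]
            shift = slots["shift"]
            diff_left = (etype == "A5") == (strand == "+")
            if diff_left:
                s, e = exons[k]
                alt_exons[k] = (s, e - shift)
                coords = {e + 1, e - shift + 1, exons[k + 1][0] - 1}
            else:
                s, e = exons[k + 1]
                alt_exons[k + 1] = (s + shift, e)
                coords = {exons[k][1] + 1, s - 1, s + shift - 1}
            sig = tuple(sorted(coords))
            # the alternative isoform has the longer intron => exclusion
            inc, exc = {f"{gid}.t1"}, {f"{gid}.t2"}
        elif etype == "MX":
            k = slots["exon"]
            alt_len = slots["alt_len"]
            a_start = exons[k][1] + margin + 1
            alt_exon = (a_start, a_start + alt_len - 1)
            alt_exons[k] = alt_exon
            first, second = sorted([exons[k], alt_exon])
            sig = (first[0], first[1], second[0], second[1])
            five = first if strand == "+" else second
            inc = {f"{gid}.t1"} if exons[k] == five else {f"{gid}.t2"}
            exc = {f"{gid}.t2"} if exons[k] == five else {f"{gid}.t1"}
        elif etype in ("AF", "AL"):
            alt_len = slots["alt_len"]
            left_end = (etype == "AF") == (strand == "+")
            if left_end:
                a_start = exons[0][1] + margin + 1
                alt_exon = (a_start, a_start + alt_len - 1)
                alt_exons[0] = alt_exon
                pair = [exons[0], alt_exon]
            else:
                a_end = exons[-1][0] - margin - 1
                alt_exon = (a_end - alt_len + 1, a_end)
                alt_exons[-1] = alt_exon
                pair = [exons[-1], alt_exon]
            first, second = sorted(pair)
            sig = (first[0], first[1], second[0], second[1])
            five = first if strand == "+" else second
            base_term = pair[0]
            inc = {f"{gid}.t1"} if base_term == five else {f"{gid}.t2"}
            exc = {f"{gid}.t2"} if base_term == five else {f"{gid}.t1"}
        else:
            raise ValueError(f"unknown event type {etype!r}")
        alt = TranscriptModel(f"{gid}.t2", gid, chrom, strand, tuple(sorted(alt_exons)))
        transcripts.append(alt)
        event = ASEvent(etype, gid, sig, inclusion=inc, exclusion=exc)

    gene = GeneModel(gid, chrom, strand, transcripts)
    return gene, event, extra, gene.end + cfg.intergenic_gap


# --------------------------------------------------------------------------
# sequence engineering


class _MutableGenome:
    def __init__(self) -> None:
        self.chroms: Dict[str, bytearray] = {}

    def ensure(self, chrom: str, length: int, rng: np.random.Generator) -> None:
        seq = rng.choice(_BASES, size=length)
        self.chroms[chrom] = bytearray(seq.tobytes())

    def write(self, chrom: str, start: int, seq: str) -> None:
        """Write forward-strand ``seq`` at 1-based position ``start``."""
        self.chroms[chrom][start - 1 : start - 1 + len(seq)] = seq.encode()

    def write_tx(self, t: TranscriptModel, g_start: int, g_end: int, seq: str) -> None:
        """Write ``seq`` (transcript orientation) across the genomic
        interval [g_start, g_end], which must be contiguous."""
        if t.strand == "+":
            self.write(t.chrom, g_start, seq)
        else:
            self.write(t.chrom, g_start, reverse_complement(seq))

    def freeze(self) -> GenomeSequence:
        return GenomeSequence({c: b.decode() for c, b in self.chroms.items()})


def _random_sense_codons(rng: np.random.Generator, n: int) -> str:
    """n random codons, none a stop codon."""
    codons = []
    while len(codons) < n:
        draw = rng.choice(_BASES, size=(n - len(codons), 3))
        for row in draw:
            codon = row.tobytes().decode()
            if codon not in STOPS:
                codons.append(codon)
    return "".join(codons[:n])


def _write_cds(
    genome: _MutableGenome,
    t: TranscriptModel,
    rng: np.random.Generator,
) -> Tuple[int, int, int, int]:
    """Write a stop-free coding sequence along transcript ``t``.

    Returns (cds_tx_start, cds_tx_end_inclusive, genomic start anchor,
    genomic stop-codon first-base anchor). The CDS includes its stop
    codon (package convention).
    """
    start_tx = 9
    end_tx = t.spliced_length - 16  # leave a 3' UTR
    length = end_tx - start_tx + 1
    length -= length % 3
    end_tx = start_tx + length - 1
    seq = "ATG" + _random_sense_codons(rng, length // 3 - 2) + "TAA"
    # write the codon stream across exons in transcript orientation
    tx_s = 0
    for s, e in t.exons_tx_order():
        ex_len = e - s + 1
        lo = max(start_tx, tx_s)
        hi = min(end_tx, tx_s + ex_len - 1)
        if lo <= hi:
            chunk = seq[lo - start_tx : hi - start_tx + 1]
            if t.strand == "+":
                genome.write(t.chrom, s + (lo - tx_s), chunk)
            else:
                g_hi = e - (lo - tx_s)
                genome.write(t.chrom, g_hi - len(chunk) + 1, reverse_complement(chunk))
        tx_s += ex_len
    return (
        start_tx,
        end_tx,
        tx_to_genomic(t, start_tx),
        tx_to_genomic(t, end_tx - 2),
    )


def _engineer_retained_intron(
    genome: _MutableGenome,
    gene: GeneModel,
    retained: Tuple[int, int],
    cds_start_tx_base: int,
    make_ptc: bool,
) -> None:
    """Fill a retained intron so the retaining isoform is PTC+ or PTC-.

    The intron (length 3n) is written as GT + C-fill + AG, which cannot
    form a stop codon in any frame; for PTC+ an in-frame TAA is placed
    inside the fill, computed in the retaining isoform's reading frame.
    """
    base, alt = gene.transcripts[0], gene.transcripts[1]
    ri_s, ri_e = retained
    L = ri_e - ri_s + 1
    assert L % 3 == 0 and L >= 12
    fill = "GT" + "C" * (L - 4) + "AG"
    if make_ptc:
        start_g = tx_to_genomic(base, cds_start_tx_base)
        start_alt_tx = genomic_to_tx(alt, start_g)
        intron_first_g = ri_s if gene.strand == "+" else ri_e
        intron_tx = genomic_to_tx(alt, intron_first_g)
        d = (intron_tx - start_alt_tx) % 3
        q = 3 if d == 0 else 3 - d + 3  # first in-frame offset >= 3
        fill = fill[:q] + "TAA" + fill[q + 3 :]
        assert len(fill) == L and fill.startswith("GT") and fill.endswith("AG")
    alt_like = TranscriptModel(
        "tmp", gene.gene_id, gene.chrom, gene.strand, ((ri_s, ri_e),)
    )
    genome.write_tx(alt_like, ri_s, ri_e, fill)
    # guard the donor junction: a codon split as [exon "TA" | intron "G"]
    # would terminate the retaining isoform early; forcing the last two
    # exonic bases before the intron to CC can never create a stop codon
    if gene.strand == "+":
        genome.write(gene.chrom, ri_s - 2, "CC")
    else:
        genome.write(gene.chrom, ri_e + 1, "GG")


def _write_splice_sites(
    genome: _MutableGenome,
    genes: Sequence[GeneModel],
    retained: Dict[str, Tuple[int, int]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> List[dict]:
    """Plant donor/acceptor dinucleotides for every unique intron.

    The noncanonical quota (largest-remainder on the unique-intron count)
    is drawn from introns whose terminal positions are not shared with
    any other intron and that are not engineered retained introns, so no
    position is written twice with conflicting bases.
    """
    introns: List[Tuple[str, str, int, int, str]] = []
    donor_pos: Dict[Tuple[str, int], int] = {}
    acceptor_pos: Dict[Tuple[str, int], int] = {}
    retained_set = {(iv[0], iv[1]) for iv in retained.values()}
    for g in genes:
        seen = set()
        for t in g.transcripts:
            for i in introns_of(t):
                key = (g.chrom, i.start, i.end)
                if key in seen:
                    continue
                seen.add(key)
                introns.append((g.gene_id, g.chrom, i.start, i.end, g.strand))
                dkey = (g.chrom, i.start if g.strand == "+" else i.end)
                akey = (g.chrom, i.end if g.strand == "+" else i.start)
                donor_pos[dkey] = donor_pos.get(dkey, 0) + 1
                acceptor_pos[akey] = acceptor_pos.get(akey, 0) + 1

    introns.sort(key=lambda x: (x[1], x[2], x[3], x[0]))
    n_total = len(introns)
    alloc = largest_remainder(
        n_total,
        {"canonical": cfg.canonical_fraction, "noncanonical": 1 - cfg.canonical_fraction},
    )
    n_noncanon = alloc["noncanonical"]

    def unshared(rec) -> bool:
        _, chrom, s, e, strand = rec
        if (chrom, s, e) in retained_set:
            return False
        dkey = (chrom, s if strand == "+" else e)
        akey = (chrom, e if strand == "+" else s)
        return donor_pos[dkey] == 1 and acceptor_pos[akey] == 1

    candidates = [i for i, rec in enumerate(introns) if unshared(rec)]
    if len(candidates) < n_noncanon:
        raise ValueError(
            "not enough independent introns to satisfy the noncanonical quota"
        )
    chosen = set(rng.choice(candidates, size=n_noncanon, replace=False).tolist())

    truth = []
    for idx, (gid, chrom, s, e, strand) in enumerate(introns):
        if idx in chosen:
            d, a = NONCANONICAL_SITES[int(rng.integers(len(NONCANONICAL_SITES)))]
        else:
            d, a = "GT", "AG"
        if strand == "+":
            genome.write(chrom, s, d)
            genome.write(chrom, e - 1, a)
        else:
            genome.write(chrom, e - 1, reverse_complement(d))
            genome.write(chrom, s, reverse_complement(a))
        truth.append(
            {"gene_id": gid, "chrom": chrom, "start": s, "end": e, "strand": strand, "donor": d, "acceptor": a}
        )
    return truth


# --------------------------------------------------------------------------
# top-level simulation


def simulate_annotation(
    config: SimulationConfig,
) -> Tuple[GenomeSequence, List[GeneModel], SimulationTruth]:
    """Generate genome, gene models and planted truth for one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = SimulationTruth(seed=config.seed)

    n_as = int(round(config.fraction_as * config.n_genes))
    type_counts = largest_remainder(n_as, config.event_proportions)
    type_queue: List[Optional[str]] = []
    for etype in sorted(type_counts):
        type_queue.extend([etype] * type_counts[etype])
    type_queue.extend([None] * (config.n_genes - n_as))
    # interleave AS and non-AS genes deterministically
    perm = rng.permutation(len(type_queue))
    assigned = [type_queue[i] for i in perm]

    genes: List[GeneModel] = []
    retained: Dict[str, Tuple[int, int]] = {}
    ir_genes: List[str] = []
    chrom_spans: Dict[str, int] = {}
    gene_meta: List[Tuple[GeneModel, Optional[ASEvent], Dict]] = []

    offset = 0
    chrom_i = 0
    for i, etype in enumerate(assigned):
        if i % config.genes_per_chromosome == 0:
            chrom_i += 1
            offset = 0
        chrom = f"chr{chrom_i}"
        gid = f"G{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene, event, extra, offset = _build_gene(
            gid, chrom, offset, strand, etype, rng, config
        )
        genes.append(gene)
        gene_meta.append((gene, event, extra))
        if event is not None:
            truth.events.append(event)
            truth.as_genes.add(gid)
        if "retained_intron" in extra:
            retained[gid] = extra["retained_intron"]
            ir_genes.append(gid)
        chrom_spans[chrom] = max(chrom_spans.get(chrom, 0), gene.end + config.intergenic_gap)

    genome = _MutableGenome()
    for chrom, span in sorted(chrom_spans.items()):
        genome.ensure(chrom, span, rng)

    # PTC engineering: exact PTC+ allocation over retained-intron isoforms
    n_plus = largest_remainder(
        len(ir_genes),
        {"plus": config.ptc_plus_fraction, "minus": 1 - config.ptc_plus_fraction},
    )["plus"]
    plus_set = set(ir_genes[:n_plus])

    cds_anchors: Dict[str, Tuple[int, int]] = {}
    for gene, event, extra in gene_meta:
        if gene.gene_id not in retained:
            continue
        base = gene.transcripts[0]
        start_tx, end_tx, g_start, g_stop = _write_cds(genome, base, rng)
        cds_span = (
            min(tx_to_genomic(base, start_tx), tx_to_genomic(base, end_tx)),
            max(tx_to_genomic(base, start_tx), tx_to_genomic(base, end_tx)),
        )
        cds_anchors[gene.gene_id] = (start_tx, end_tx)
        # re-attach CDS to the base transcript
        new_base = TranscriptModel(
            base.transcript_id, base.gene_id, base.chrom, base.strand, base.exons, cds=cds_span
        )
        gene.transcripts[0] = new_base
        make_ptc = gene.gene_id in plus_set
        _engineer_retained_intron(
            genome, gene, retained[gene.gene_id], start_tx, make_ptc
        )
        truth.ptc_status[f"{gene.gene_id}.t2"] = {
            "gene_id": gene.gene_id,
            "intron": retained[gene.gene_id],
            "status": "PTC+" if make_ptc else "PTC-",
        }

    truth.splice_sites = _write_splice_sites(genome, genes, retained, config, rng)

    return genome.freeze(), genes, truth


def simulate_expression(
    genes: Sequence[GeneModel],
    truth: SimulationTruth,
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, str]]:
    """Tissue-structured FPKM matrices with planted modules and hubs.

    Returns (transcript FPKM, gene FPKM, sample -> tissue map). Module
    membership is planted on the gene level: member genes load on a
    module eigengene with the configured correlation, hub genes with the
    (higher) hub correlation. Planted tissue-specific transcripts are
    strongly expressed in exactly one tissue and silent elsewhere; all
    other transcripts are floored above the presence threshold in every
    tissue so specificity recovery is exact.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    samples = [
        f"{t}_{r + 1}" for t in config.tissues for r in range(config.n_replicates)
    ]
    tissue_map = {s: s.rsplit("_", 1)[0] for s in samples}
    n_samples = len(samples)
    tissue_idx = np.array(
        [list(config.tissues).index(tissue_map[s]) for s in samples]
    )

    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)

    # module memberships: contiguous blocks of genes, first member is the hub
    module_of = np.zeros(n_genes, dtype=int)
    hub_flags = np.zeros(n_genes, dtype=bool)
    pos = 0
    for m in range(1, config.n_modules + 1):
        module_of[pos : pos + config.module_size] = m
        hub_flags[pos] = True
        pos += config.module_size

    # module eigengenes: a distinct tissue profile per module plus
    # replicate jitter; eigengenes are orthogonalized (Gram-Schmidt) so
    # between-module correlation is exactly zero by construction
    eigen = np.zeros((config.n_modules, n_samples))
    for m in range(config.n_modules):
        profile = rng.normal(0.0, 1.0, size=len(config.tissues))
        e = profile[tissue_idx] + rng.normal(
            0.0, config.replicate_noise_sd, size=n_samples
        )
        e = e - e.mean()
        for prev in range(m):
            e = e - (e @ eigen[prev]) / (eigen[prev] @ eigen[prev]) * eigen[prev]
        eigen[m] = (e - e.mean()) / e.std()

    z = np.zeros((n_genes, n_samples))
    for i in range(n_genes):
        noise = rng.normal(0.0, 1.0, size=n_samples)
        m = module_of[i]
        if m == 0:
            z[i] = noise
        else:
            r = config.hub_cor if hub_flags[i] else config.within_module_cor
            z[i] = math.sqrt(r) * eigen[m - 1] + math.sqrt(1.0 - r) * noise

    # map latent scores to FPKM: roughly log-normal around 10
    gene_fpkm = np.power(10.0, 1.0 + 0.5 * z)
    gene_df = pd.DataFrame(gene_fpkm, index=gene_ids, columns=samples)

    for i, gid in enumerate(gene_ids):
        m = module_of[i]
        if m > 0:
            truth.modules[gid] = int(m)
            if hub_flags[i]:
                truth.hubs.add(gid)

    # transcript level: isoforms share the gene signal with multiplicative
    # noise, floored above the presence threshold so only the planted
    # tissue-specific and low-expression transcripts break ubiquity
    tx_rows = []
    tx_ids = []
    all_tx = [(g, t) for g in genes for t in g.transcripts]
    n_specific = int(round(config.fraction_tissue_specific * len(all_tx)))
    # choose non-IR-alternative transcripts for specificity/low expression
    ir_alt = set(truth.ptc_status)
    eligible = [t.transcript_id for g, t in all_tx if t.transcript_id not in ir_alt]
    specific_ids = set(
        rng.choice(eligible, size=min(n_specific, len(eligible)), replace=False).tolist()
    )
    n_low = int(round(config.low_expression_fraction * len(ir_alt)))
    low_ids = set(sorted(ir_alt)[:n_low])
    truth.low_expression = low_ids

    gene_index = {gid: i for i, gid in enumerate(gene_ids)}
    for g, t in all_tx:
        tid = t.transcript_id
        tx_ids.append(tid)
        if tid in low_ids:
            row = rng.uniform(0.0, 0.5, size=n_samples)
        elif tid in specific_ids:
            k = int(rng.integers(len(config.tissues)))
            truth.tissue_specific[tid] = config.tissues[k]
            row = rng.uniform(0.0, 0.3, size=n_samples)
            sel = tissue_idx == k
            row[sel] = rng.uniform(5.0, 20.0, size=int(sel.sum()))
        else:
            base = gene_fpkm[gene_index[g.gene_id]]
            row = base * np.power(2.0, rng.normal(0.0, 0.25, size=n_samples))
            row = np.maximum(row, 1.5)  # ubiquitously present
        tx_rows.append(row)
    tx_df = pd.DataFrame(np.vstack(tx_rows), index=tx_ids, columns=samples)
    return tx_df, gene_df, tissue_map


def simulate_bundle(config: SimulationConfig, outdir: Optional[str] = None):
    """Full simulation: annotation, genome, expression, truth.

    With ``outdir`` the standard file bundle is written: genome.fa,
    annotation.gtf, fpkm_transcripts.tsv, fpkm_genes.tsv, tissue_map.yaml
    and truth/*.tsv.
    """
    genome, genes, truth = simulate_annotation(config)
    tx_df, gene_df, tissue_map = simulate_expression(genes, truth, config)
    if outdir is not None:
        import os

        import yaml

        from .annotation_io import write_annotation, write_fasta

        os.makedirs(outdir, exist_ok=True)
        write_fasta(genome, os.path.join(outdir, "genome.fa"))
        write_annotation(genes, os.path.join(outdir, "annotation.gtf"))
        tx_df.to_csv(os.path.join(outdir, "fpkm_transcripts.tsv"), sep="\t", index_label="id")
        gene_df.to_csv(os.path.join(outdir, "fpkm_genes.tsv"), sep="\t", index_label="id")
        with open(os.path.join(outdir, "tissue_map.yaml"), "w") as fh:
            yaml.safe_dump(tissue_map, fh, sort_keys=True)
        truth.save(os.path.join(outdir, "truth"))
    return genome, genes, truth, tx_df, gene_df, tissue_map
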