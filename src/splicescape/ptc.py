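"""Premature-termination-codon classification of retained-intron isoforms.

A retained-intron transcript is PTC+ when translation from the gene's
reference start codon terminates at a stop that maps genomically
upstream (in transcript orientation) of the reference stop codon, and
PTC- otherwise. This equates PTC with "premature stop"; the classical
50-nt last-junction NMD rule is reported as an auxiliary flag, not the
verdict, since not every premature stop is an NMD target.

CDS convention: annotated CDS spans in this package include the stop
codon, so the reference stop anchors at the final three coding bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .expression import ExpressionMatrix
from .models import GeneModel, GenomeSequence, TranscriptModel, spliced_sequence

__all__ = [
    "ReferenceORF",
    "PTCCall",
    "PTCCensus",
    "reference_orf",
    "classify_ptc",
    "expression_filter",
    "ptc_census",
    "write_ptc_table",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


def tx_to_genomic(t: TranscriptModel, pos: int) -> int:
    """Map a 0-based transcript coordinate to its genomic position."""
    if pos < 0 or pos >= t.spliced_length:
        raise ValueError(f"transcript position {pos} out of range")
    remaining = pos
    for s, e in t.exons_tx_order():
        length = e - s + 1
        if remaining < length:
            return s + remaining if t.strand == "+" else e - remaining
        remaining -= length
    raise AssertionError("unreachable")


def genomic_to_tx(t: TranscriptModel, gpos: int) -> Optional[int]:
    """Map a genomic position to a 0-based transcript coordinate, or None
    if the position is intronic / outside the transcript."""
    offset = 0
    for s, e in t.exons_tx_order():
        if s <= gpos <= e:
            return offset + (gpos - s if t.strand == "+" else e - gpos)
        offset += e - s + 1
    return None


@dataclass(frozen=True)
class ReferenceORF:
    """Reference reading frame of a gene, anchored genomically.

    ``start`` / ``stop`` are the genomic positions of the first base of
    the start and stop codons in transcript orientation.
    """

    gene_id: str
    transcript_id: str
    start: int
    stop: int
    strand: str


def _longest_orf(seq: str, min_codons: int) -> Optional[Tuple[int, int]]:
    """Longest ATG-initiated, stop-terminated ORF (0-based tx coords of
    start codon and stop codon first bases), or None if shorter than
    ``min_codons`` coding codons."""
    best: Optional[Tuple[int, int]] = None
    best_len = -1
    n = len(seq)
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                length = (i - start) // 3
                if length > best_len:
                    best, best_len = (start, i), length
                start = None
    if best is None or best_len < min_codons:
        return None
    return best


def reference_orf(
    gene: GeneModel, genome: GenomeSequence, min_codons: int = 100
) -> Optional[ReferenceORF]:
    """Resolve the gene's reference ORF.

    The longest annotated CDS wins; otherwise the longest ATG-initiated
    ORF (>= ``min_codons`` codons) over all isoforms. Returns None when
    neither exists (the gene's retained-intron calls are then
    undetermined).
    """
    with_cds = [t for t in gene.transcripts if t.cds is not None]
    if with_cds:
        def cds_len(t: TranscriptModel) -> int:
            cs, ce = t.cds
            return sum(
                min(e, ce) - max(s, cs) + 1
                for s, e in t.exons
                if max(s, cs) <= min(e, ce)
            )

        ref = max(with_cds, key=lambda t: (cds_len(t), t.transcript_id))
        cs, ce = ref.cds
        if ref.strand == "+":
            start_tx = genomic_to_tx(ref, cs)
            end_tx = genomic_to_tx(ref, ce)
        else:
            start_tx = genomic_to_tx(ref, ce)
            end_tx = genomic_to_tx(ref, cs)
        if start_tx is None or end_tx is None:
            raise ValueError(
                f"gene {gene.gene_id}: CDS of {ref.transcript_id} not exonic"
            )
        stop_first_tx = end_tx - 2
        return ReferenceORF(
            gene_id=gene.gene_id,
            transcript_id=ref.transcript_id,
            start=tx_to_genomic(ref, start_tx),
            stop=tx_to_genomic(ref, stop_first_tx),
            strand=ref.strand,
        )

    best: Optional[Tuple[int, TranscriptModel, Tuple[int, int]]] = None
    for t in sorted(gene.transcripts, key=lambda t: t.transcript_id):
        orf = _longest_orf(spliced_sequence(t, genome), min_codons)
        if orf is None:
            continue
        length = orf[1] - orf[0]
        if best is None or length > best[0]:
            best = (length, t, orf)
    if best is None:
        return None
    _, t, (start_tx, stop_tx) = best
    return ReferenceORF(
        gene_id=gene.gene_id,
        transcript_id=t.transcript_id,
        start=tx_to_genomic(t, start_tx),
        stop=tx_to_genomic(t, stop_tx),
        strand=t.strand,
    )


@dataclass
class PTCCall:
    """Verdict for one retained-intron transcript."""

    transcript_id: str
    gene_id: str
    intron: Tuple[int, int]
    status: str  # "PTC+", "PTC-", or "undetermined"
    orf_start_tx: Optional[int] = None
    first_stop_tx: Optional[int] = None
    nmd_50nt_flag: bool = False


def _upstream(strand: str, a: int, b: int) -> bool:
    """Is genomic position a strictly 5' of b in transcript orientation?"""
    return a < b if strand == "+" else a > b


def classify_ptc(
    t_ir: TranscriptModel,
    ref: Optional[ReferenceORF],
    genome: GenomeSequence,
    retained_intron: Tuple[int, int],
) -> PTCCall:
    """Classify a retained-intron transcript against the reference ORF.

    ``retained_intron`` is the genomic interval of the intron the
    transcript retains; it must lie inside one of its exons. Translation
    starts from the reference start codon mapped into this transcript;
    PTC+ iff the first in-frame stop lies genomically upstream (transcript
    orientation) of the reference stop codon.
    """
    ri_s, ri_e = retained_intron
    if not any(s <= ri_s and ri_e <= e for s, e in t_ir.exons):
        raise ValueError(
            f"transcript {t_ir.transcript_id} does not retain intron "
            f"({ri_s}, {ri_e})"
        )
    base = PTCCall(
        transcript_id=t_ir.transcript_id,
        gene_id=t_ir.gene_id,
        intron=(ri_s, ri_e),
        status="undetermined",
    )
    if ref is None:
        return base
    start_tx = genomic_to_tx(t_ir, ref.start)
    if start_tx is None:
        return base
    seq = spliced_sequence(t_ir, genome)
    first_stop_tx: Optional[int] = None
    for i in range(start_tx, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            first_stop_tx = i
            break
    base.orf_start_tx = start_tx
    if first_stop_tx is None:
        # read-through past the annotated stop: no premature termination
        base.status = "PTC-"
        return base
    base.first_stop_tx = first_stop_tx
    stop_genomic = tx_to_genomic(t_ir, first_stop_tx)
    if _upstream(t_ir.strand, stop_genomic, ref.stop):
        base.status = "PTC+"
        # auxiliary 50-nt rule: premature stop more than 50 nt upstream of
        # the final exon-exon junction
        if t_ir.n_exons > 1:
            last_exon = t_ir.exons_tx_order()[-1]
            junction_tx = t_ir.spliced_length - (last_exon[1] - last_exon[0] + 1)
            base.nmd_50nt_flag = junction_tx - (first_stop_tx + 3) > 50
    else:
        base.status = "PTC-"
    return base


def expression_filter(
    transcript_ids: Sequence[str], expr: ExpressionMatrix, min_fpkm: float = 1.0
) -> List[str]:
    """Transcripts expressed (mean replicate FPKM >= threshold) in at
    least one tissue; the rest are discarded."""
    presence = expr.tissue_presence(min_fpkm=min_fpkm)
    kept = []
    for tid in transcript_ids:
        if tid not in presence.index:
            raise ValueError(f"no expression row for transcript {tid!r}")
        if bool(presence.loc[tid].any()):
            kept.append(tid)
    return kept


@dataclass
class PTCCensus:
    """Per-tissue and cross-tissue tallies of PTC+/PTC- transcripts."""

    per_tissue: Dict[str, Dict[str, int]]
    shared: Dict[str, int]
    specific: Dict[str, Dict[str, int]]
    n_plus: int
    n_minus: int

    @property
    def ratio(self) -> Optional[float]:
        if self.n_minus == 0:
            return None
        return self.n_plus / self.n_minus


def ptc_census(
    calls: Sequence[PTCCall], expr: ExpressionMatrix, min_fpkm: float = 1.0
) -> PTCCensus:
    """Tally resolved PTC calls by tissue presence.

    A transcript counts in a tissue iff present there (mean replicate
    FPKM >= threshold); "shared" means present in every tissue and
    "specific" in exactly one.
    """
    presence = expr.tissue_presence(min_fpkm=min_fpkm)
    tissues = list(presence.columns)
    per_tissue = {t: {"PTC+": 0, "PTC-": 0} for t in tissues}
    shared = {"PTC+": 0, "PTC-": 0}
    specific = {t: {"PTC+": 0, "PTC-": 0} for t in tissues}
    n_plus = n_minus = 0
    for call in calls:
        if call.status not in ("PTC+", "PTC-"):
            continue
        if call.transcript_id not in presence.index:
            continue
        row = presence.loc[call.transcript_id]
        n_present = int(row.sum())
        if n_present == 0:
            continue
        if call.status == "PTC+":
            n_plus += 1
        else:
            n_minus += 1
        for t in tissues:
            if bool(row[t]):
                per_tissue[t][call.status] += 1
        if n_present == len(tissues):
            shared[call.status] += 1
        elif n_present == 1:
            specific[row.idxmax()][call.status] += 1
    return PTCCensus(
        per_tissue=per_tissue,
        shared=shared,
        specific=specific,
        n_plus=n_plus,
        n_minus=n_minus,
    )


def write_ptc_table(calls: Sequence[PTCCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tgene_id\tintron_start\tintron_end\tstatus\tnmd_50nt_flag\n"
        )
        for c in sorted(calls, key=lambda c: c.transcript_id):
            fh.write(
                f"{c.transcript_id}\t{c.gene_id}\t{c.intron[0]}\t{c.intron[1]}\t"
                f"{c.status}\t{int(c.nmd_50nt_flag)}\n"
            )
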