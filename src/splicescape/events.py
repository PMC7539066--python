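"""Seven-type alternative-splicing event enumeration from isoform models.

Events are called per gene by exhaustive pairwise comparison of its
isoforms and deduplicated by (gene, type, coordinate signature), so an
event supported by several isoform pairs is counted once with the union
of its supporting transcript sets.

Event definitions (all coordinates genomic, 1-based closed; "5'"/"3'"
refer to transcript orientation):

IR  intron retention       — an intron of the spliced form lies inside a
    single exon of the retaining form whose boundaries equal the outer
    edges of the spliced form's flanking exons.
ES  exon skipping          — an internal exon of the inclusion form lies
    strictly inside an intron of the skipping form whose boundaries
    match the inclusion form's flanking splice sites.
A5 / A3                    — two introns share one boundary and differ at
    the other; the exons flanking the differing boundary must overlap
    (otherwise the difference is an alternative terminal exon, not an
    alternative splice site). A5 when the differing side is the donor
    (5'), A3 when it is the acceptor (3').
MX  mutually exclusive     — each isoform has exactly one internal exon
    between a shared upstream donor and shared downstream acceptor, and
    the two internal exons do not overlap.
AF / AL                    — distinct, non-overlapping first (AF) or last
    (AL) exons whose adjacent introns share the internal-side boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .models import GeneModel, TranscriptModel, introns_of

__all__ = [
    "ASEvent",
    "EventSummary",
    "EVENT_TYPES",
    "enumerate_events",
    "enumerate_all",
    "classify_genes",
    "event_summary",
    "tissue_specific_sets",
    "write_event_table",
]

EVENT_TYPES = ("IR", "ES", "A3", "A5", "AF", "AL", "MX")


@dataclass
class ASEvent:
    """One deduplicated alternative-splicing event."""

    event_type: str
    gene_id: str
    signature: Tuple[int, ...]
    inclusion: Set[str] = field(default_factory=set)
    exclusion: Set[str] = field(default_factory=set)

    @property
    def event_id(self) -> str:
        coords = "-".join(str(c) for c in self.signature)
        return f"{self.gene_id}:{self.event_type}:{coords}"

    def key(self) -> Tuple[str, str, Tuple[int, ...]]:
        return (self.gene_id, self.event_type, self.signature)


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _pair_events(x: TranscriptModel, y: TranscriptModel) -> List[ASEvent]:
    """Events visible in one ordered comparison (x = spliced/inclusion role)."""
    out: List[ASEvent] = []
    gid = x.gene_id
    strand = x.strand
    xi = introns_of(x)
    y_exons = set(y.exons)
    y_introns = {(i.start, i.end) for i in introns_of(y)}

    # --- IR: intron of x retained inside an exon of y -------------------
    for k, intr in enumerate(xi):
        up, down = x.exons[k], x.exons[k + 1]
        if (up[0], down[1]) in y_exons:
            out.append(
                ASEvent(
                    "IR",
                    gid,
                    (up[1], down[0]),
                    inclusion={y.transcript_id},  # retains the intron
                    exclusion={x.transcript_id},
                )
            )

    # --- ES: internal exon of x skipped by an intron of y ---------------
    for k in range(1, x.n_exons - 1):
        up, mid, down = x.exons[k - 1], x.exons[k], x.exons[k + 1]
        if (up[1] + 1, down[0] - 1) in y_introns:
            out.append(
                ASEvent(
                    "ES",
                    gid,
                    (up[1], mid[0], mid[1], down[0]),
                    inclusion={x.transcript_id},
                    exclusion={y.transcript_id},
                )
            )

    # --- A5 / A3: introns sharing exactly one boundary ------------------
    yj = introns_of(y)
    for a, ia in enumerate(xi):
        for b, ib in enumerate(yj):
            same_start = ia.start == ib.start
            same_end = ia.end == ib.end
            if same_start == same_end:  # identical or fully distinct
                continue
            if same_end:
                # differ at genomic-left boundary; flanking exons on that side
                fx, fy = x.exons[a], y.exons[b]
                diff_left = True
            else:
                fx, fy = x.exons[a + 1], y.exons[b + 1]
                diff_left = False
            if not _overlap(fx, fy):
                continue  # alternative terminal exon territory, not A5/A3
            # genomic-left boundary is the donor on '+', acceptor on '-'
            etype = ("A5" if diff_left else "A3") if strand == "+" else (
                "A3" if diff_left else "A5"
            )
            sig = tuple(sorted({ia.start, ia.end, ib.start, ib.end}))
            shorter, longer = (
                (x, y) if (ia.end - ia.start) < (ib.end - ib.start) else (y, x)
            )
            out.append(
                ASEvent(
                    etype,
                    gid,
                    sig,
                    inclusion={shorter.transcript_id},  # shorter intron keeps more exon
                    exclusion={longer.transcript_id},
                )
            )

    # --- MX: one internal exon each between shared flank boundaries -----
    for k in range(1, x.n_exons - 1):
        ux, mx_exon, dx = x.exons[k - 1], x.exons[k], x.exons[k + 1]
        for j in range(1, y.n_exons - 1):
            uy, my_exon, dy = y.exons[j - 1], y.exons[j], y.exons[j + 1]
            if ux[1] != uy[1] or dx[0] != dy[0]:
                continue
            if _overlap(mx_exon, my_exon):
                continue
            first, second = sorted([mx_exon, my_exon])
            sig = (first[0], first[1], second[0], second[1])
            # inclusion = isoform whose internal exon is transcript-5'-most
            five_prime_exon = first if strand == "+" else second
            inc = x if mx_exon == five_prime_exon else y
            exc = y if inc is x else x
            out.append(
                ASEvent(
                    "MX",
                    gid,
                    sig,
                    inclusion={inc.transcript_id},
                    exclusion={exc.transcript_id},
                )
            )

    # --- AF / AL: alternative non-overlapping terminal exons ------------
    for etype in ("AF", "AL"):
        if x.n_exons < 2 or y.n_exons < 2:
            continue
        first_like = (etype == "AF") == (strand == "+")
        if first_like:
            # terminal exon at genomic-left end; shared boundary = start of
            # the second exon (the adjacent intron's internal-side edge)
            tx_term, tx_anchor = x.exons[0], x.exons[1][0]
            ty_term, ty_anchor = y.exons[0], y.exons[1][0]
        else:
            tx_term, tx_anchor = x.exons[-1], x.exons[-2][1]
            ty_term, ty_anchor = y.exons[-1], y.exons[-2][1]
        if tx_anchor != ty_anchor:
            continue
        if tx_term == ty_term or _overlap(tx_term, ty_term):
            continue
        first, second = sorted([tx_term, ty_term])
        sig = (first[0], first[1], second[0], second[1])
        # inclusion = isoform whose terminal exon is transcript-5'-most
        five_prime_exon = first if strand == "+" else second
        inc = x if tx_term == five_prime_exon else y
        exc = y if inc is x else x
        out.append(
            ASEvent(
                etype,
                gid,
                sig,
                inclusion={inc.transcript_id},
                exclusion={exc.transcript_id},
            )
        )

    return out


def enumerate_events(gene: GeneModel) -> List[ASEvent]:
    """All deduplicated AS events of one gene.

    Every unordered isoform pair is compared in both directions;
    duplicate (type, signature) calls are merged by unioning their
    inclusion and exclusion transcript sets. A single-transcript gene
    yields an empty list. Output order is deterministic: by type, then
    signature.
    """
    merged: Dict[Tuple[str, str, Tuple[int, ...]], ASEvent] = {}
    txs = sorted(gene.transcripts, key=lambda t: t.transcript_id)
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            for ev in _pair_events(txs[i], txs[j]) + _pair_events(txs[j], txs[i]):
                key = ev.key()
                if key in merged:
                    merged[key].inclusion |= ev.inclusion
                    merged[key].exclusion |= ev.exclusion
                else:
                    merged[key] = ev
    events = sorted(merged.values(), key=lambda e: (e.event_type, e.signature))
    for ev in events:
        # a transcript supporting both roles for the same signature would be
        # contradictory; resolution: the inclusion role wins
        ev.exclusion -= ev.inclusion
    return [e for e in events if e.inclusion and e.exclusion]


def enumerate_all(genes: Iterable[GeneModel]) -> List[ASEvent]:
    """Enumerate events over a gene collection (genes treated independently)."""
    out: List[ASEvent] = []
    for g in genes:
        out.extend(enumerate_events(g))
    return out


def classify_genes(
    genes: Sequence[GeneModel], events: Sequence[ASEvent]
) -> Tuple[Dict[str, bool], float]:
    """Flag each gene as alternatively spliced and give the AS-gene percent.

    A gene is AS iff at least one event references it. Returns
    (gene_id -> bool, percent of genes that are AS).
    """
    known = {g.gene_id for g in genes}
    flags = {gid: False for gid in known}
    for ev in events:
        if ev.gene_id not in known:
            raise ValueError(f"event references unknown gene {ev.gene_id!r}")
        flags[ev.gene_id] = True
    if not flags:
        return {}, 0.0
    pct = 100.0 * sum(flags.values()) / len(flags)
    return flags, pct


@dataclass
class EventSummary:
    """Per-type event counts with proportions of the total (percent)."""

    counts: Dict[str, int]
    total: int
    proportions: Dict[str, float]

    @property
    def empty(self) -> bool:
        return self.total == 0


def event_summary(events_or_counts) -> EventSummary:
    """Summarize events (or a per-type count mapping) into counts and
    percentages reported to two decimals."""
    if isinstance(events_or_counts, Mapping):
        counts = {t: int(events_or_counts.get(t, 0)) for t in EVENT_TYPES}
    else:
        counts = {t: 0 for t in EVENT_TYPES}
        for ev in events_or_counts:
            counts[ev.event_type] += 1
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative event count")
    total = sum(counts.values())
    if total == 0:
        return EventSummary(counts=counts, total=0, proportions={t: 0.0 for t in EVENT_TYPES})
    props = {t: round(100.0 * c / total, 2) for t, c in counts.items()}
    return EventSummary(counts=counts, total=total, proportions=props)


def tissue_specific_sets(
    events: Sequence[ASEvent],
    genes: Sequence[GeneModel],
    expr,
    min_fpkm: float = 1.0,
    gene_expr=None,
) -> Dict[str, Dict[str, Set[str]]]:
    """Tissue-specific AS genes and AS transcripts.

    An AS transcript (any transcript referenced by an event) or AS gene is
    tissue-specific iff it is present — mean replicate FPKM >= ``min_fpkm``
    — in exactly one tissue. ``expr`` is the transcript-level
    :class:`~splicescape.expression.ExpressionMatrix`; gene presence is
    taken from ``gene_expr`` when given, otherwise a gene is present in a
    tissue iff any of its transcripts is.
    """
    as_tx: Set[str] = set()
    as_genes: Set[str] = set()
    for ev in events:
        as_tx |= ev.inclusion | ev.exclusion
        as_genes.add(ev.gene_id)

    presence = expr.tissue_presence(min_fpkm=min_fpkm)
    tissues = list(presence.columns)

    missing = as_tx - set(presence.index)
    if missing:
        raise ValueError(
            f"no expression rows for transcripts: {sorted(missing)[:5]}..."
        )

    tx_specific: Dict[str, Set[str]] = {t: set() for t in tissues}
    for tid in sorted(as_tx):
        row = presence.loc[tid]
        if int(row.sum()) == 1:
            tx_specific[row.idxmax()].add(tid)

    gene_specific: Dict[str, Set[str]] = {t: set() for t in tissues}
    if gene_expr is not None:
        gpres = gene_expr.tissue_presence(min_fpkm=min_fpkm)
        for gid in sorted(as_genes):
            row = gpres.loc[gid]
            if int(row.sum()) == 1:
                gene_specific[row.idxmax()].add(gid)
    else:
        tx_by_gene: Dict[str, List[str]] = {}
        for g in genes:
            if g.gene_id in as_genes:
                tx_by_gene[g.gene_id] = [
                    t.transcript_id
                    for t in g.transcripts
                    if t.transcript_id in presence.index
                ]
        for gid, tids in sorted(tx_by_gene.items()):
            if not tids:
                continue
            gp = presence.loc[tids].any(axis=0)
            if int(gp.sum()) == 1:
                gene_specific[gp.idxmax()].add(gid)

    return {"transcripts": tx_specific, "genes": gene_specific}


def write_event_table(events: Sequence[ASEvent], path: str, strand_of=None) -> None:
    """TSV export: gene_id, event_id, type, signature, transcript sets."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tevent_id\tevent_type\tsignature\t"
            "inclusion_transcripts\texclusion_transcripts\n"
        )
        for ev in sorted(events, key=lambda e: (e.gene_id, e.event_type, e.signature)):
            sig = "-".join(str(c) for c in ev.signature)
            fh.write(
                f"{ev.gene_id}\t{ev.event_id}\t{ev.event_type}\t{sig}\t"
                f"{','.join(sorted(ev.inclusion))}\t{','.join(sorted(ev.exclusion))}\n"
            )
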