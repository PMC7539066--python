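"""Gene-structure statistics and their relationship with splicing status.

Each gene is summarized by a representative isoform — the transcript
with the most exons, ties broken by spliced length then id — because
per-gene exon/intron metrics need a single structure. Undefined
averages (intron metrics of single-exon genes) are reported as missing
and excluded from group statistics rather than zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .events import ASEvent
from .models import GeneModel, GenomeSequence, TranscriptModel, introns_of, spliced_sequence
from .ptc import _longest_orf

__all__ = [
    "feature_table",
    "compare_groups",
    "events_vs_structure",
    "features_by_event_type",
    "flag_noncoding",
]

QUANTILE_METHOD = "linear"  # interpolation used for all box statistics

_METRICS = [
    "transcript_length",
    "exon_count",
    "intron_count",
    "total_exon_length",
    "total_intron_length",
    "avg_exon_length",
    "avg_intron_length",
]


def _representative(g: GeneModel) -> TranscriptModel:
    return max(
        g.transcripts,
        key=lambda t: (t.n_exons, t.spliced_length, t.transcript_id),
    )


def feature_table(
    genes: Sequence[GeneModel], events: Sequence[ASEvent]
) -> pd.DataFrame:
    """One row per gene: structural metrics, AS flag, event count/types."""
    ev_count: Dict[str, int] = {}
    ev_types: Dict[str, set] = {}
    for ev in events:
        ev_count[ev.gene_id] = ev_count.get(ev.gene_id, 0) + 1
        ev_types.setdefault(ev.gene_id, set()).add(ev.event_type)

    rows = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        t = _representative(g)
        introns = introns_of(t)
        exon_lens = [e - s + 1 for s, e in t.exons]
        intron_lens = [i.length for i in introns]
        rows.append(
            {
                "gene_id": g.gene_id,
                "transcript_length": t.spliced_length,
                "exon_count": t.n_exons,
                "intron_count": len(introns),
                "total_exon_length": sum(exon_lens),
                "total_intron_length": sum(intron_lens) if intron_lens else np.nan,
                "avg_exon_length": float(np.mean(exon_lens)),
                "avg_intron_length": (
                    float(np.mean(intron_lens)) if intron_lens else np.nan
                ),
                "as_flag": g.gene_id in ev_count,
                "event_count": ev_count.get(g.gene_id, 0),
                "event_types": ",".join(sorted(ev_types.get(g.gene_id, ()))),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def compare_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Quantile summary (median, Q1, Q3, P5, P95) of every structural
    metric, split by AS status. Missing values are excluded per metric.

    Quantiles use linear interpolation so the box statistics are exactly
    reproducible.
    """
    groups = {"AS": records[records["as_flag"]], "non-AS": records[~records["as_flag"]]}
    for name, df in groups.items():
        if df.empty:
            raise ValueError(f"group {name!r} is empty")
    out = []
    for name, df in groups.items():
        for metric in _METRICS:
            vals = df[metric].dropna()
            if vals.empty:
                continue
            q = np.quantile(vals, [0.05, 0.25, 0.5, 0.75, 0.95], method=QUANTILE_METHOD)
            out.append(
                {
                    "group": name,
                    "metric": metric,
                    "n": len(vals),
                    "p5": q[0],
                    "q1": q[1],
                    "median": q[2],
                    "q3": q[3],
                    "p95": q[4],
                }
            )
    return pd.DataFrame(out)


def events_vs_structure(
    records: pd.DataFrame, max_bin: int = 10
) -> pd.DataFrame:
    """Mean structural metrics per AS-event-count bin (1, 2, ..., >=max_bin).

    Only AS genes contribute; the last bin pools all genes with at least
    ``max_bin`` events.
    """
    as_rec = records[records["as_flag"]].copy()
    binned = as_rec["event_count"].clip(upper=max_bin)
    out = []
    for b in sorted(binned.unique()):
        sub = as_rec[binned == b]
        row = {"event_count_bin": (f">={max_bin}" if b == max_bin else str(int(b))),
               "n_genes": len(sub)}
        for metric in _METRICS:
            row[f"mean_{metric}"] = float(sub[metric].dropna().mean())
        out.append(row)
    return pd.DataFrame(out)


def features_by_event_type(
    records: pd.DataFrame, events: Sequence[ASEvent]
) -> pd.DataFrame:
    """Per-event-type mean and median of average exon length, average
    intron length, and exon count. A gene contributes to every event
    type it exhibits."""
    by_type: Dict[str, List[str]] = {}
    for ev in events:
        by_type.setdefault(ev.event_type, []).append(ev.gene_id)
    out = []
    for etype in sorted(by_type):
        gids = sorted(set(by_type[etype]) & set(records.index))
        sub = records.loc[gids]
        row = {"event_type": etype, "n_genes": len(gids)}
        for metric in ("avg_exon_length", "avg_intron_length", "exon_count"):
            vals = sub[metric].dropna()
            row[f"mean_{metric}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"median_{metric}"] = float(vals.median()) if len(vals) else np.nan
        out.append(row)
    return pd.DataFrame(out)


def flag_noncoding(
    t: TranscriptModel,
    genome: GenomeSequence,
    min_len: int = 200,
    max_orf_codons: int = 100,
) -> bool:
    """Putative-noncoding flag: spliced length >= ``min_len`` and longest
    ATG-initiated ORF shorter than ``max_orf_codons`` codons.

    A deliberately simple ORF-length rule standing in for dedicated
    coding-potential classifiers: long transcripts with no substantial
    reading frame are flagged as lncRNA candidates.
    """
    if t.spliced_length < min_len:
        return False
    seq = spliced_sequence(t, genome)
    orf = _longest_orf(seq, min_codons=0)
    if orf is None:
        return True
    start, stop = orf
    return (stop - start) // 3 < max_orf_codons
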