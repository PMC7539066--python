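"""End-to-end orchestration: events -> PTC -> splice sites -> features ->
expression -> coexpression, with per-stage TSV outputs, a combined
summary, and a machine-readable run manifest for exact replay."""

from __future__ import annotations

import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation_io import read_annotation, read_fasta
from .coexpression import coexpression_analysis
from .events import (
    classify_genes,
    enumerate_all,
    event_summary,
    tissue_specific_sets,
    write_event_table,
)
from .expression import ExpressionMatrix, read_fpkm, read_tissue_map, variance_top_fraction
from .features import compare_groups, feature_table, flag_noncoding
from .models import GeneModel, GenomeSequence
from .ptc import classify_ptc, expression_filter, ptc_census, reference_orf, write_ptc_table
from .splice_sites import site_proportions, write_profile

logger = logging.getLogger("splicescape")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    gtf: str
    fasta: str
    fpkm_transcripts: str
    fpkm_genes: Optional[str] = None
    tissue_map: Optional[str] = None
    outdir: str = "splicescape_out"
    min_fpkm: float = 1.0
    power: Optional[float] = 16.0
    min_module_size: int = 300
    hub_fraction: float = 0.10
    variance_fraction: float = 0.60
    cut_height: Optional[float] = None
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # partial outputs are retained on disk
                raise StageError(name, exc) from exc
            logger.info("stage %s: done in %.2fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Run all analysis stages and return the summary dictionary.

    Per-stage TSVs, summary.json and manifest.json are written under
    ``cfg.outdir``. Reruns with the same manifest reproduce identical
    outputs.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    out = lambda name: os.path.join(cfg.outdir, name)

    genome = _stage("load-genome")(read_fasta)(cfg.fasta)
    genes = _stage("load-annotation")(read_annotation)(cfg.gtf, genome)

    tissue_map = read_tissue_map(cfg.tissue_map) if cfg.tissue_map else None
    tx_expr = _stage("load-expression")(read_fpkm)(cfg.fpkm_transcripts, tissue_map)
    gene_expr = (
        _stage("load-gene-expression")(read_fpkm)(cfg.fpkm_genes, tissue_map)
        if cfg.fpkm_genes
        else None
    )

    # --- events ----------------------------------------------------------
    events = _stage("events")(enumerate_all)(genes)
    write_event_table(events, out("events.tsv"))
    flags, as_pct = classify_genes(genes, events)
    summary_ev = event_summary(events)

    # --- PTC -------------------------------------------------------------
    @_stage("ptc")
    def _ptc():
        gene_by_id = {g.gene_id: g for g in genes}
        tx_by_id = {t.transcript_id: t for g in genes for t in g.transcripts}
        ir_pairs = []  # (transcript, retained intron)
        for ev in events:
            if ev.event_type != "IR":
                continue
            intron = (ev.signature[0] + 1, ev.signature[1] - 1)
            for tid in sorted(ev.inclusion):
                ir_pairs.append((tid, intron))
        kept = set(
            expression_filter(
                sorted({tid for tid, _ in ir_pairs}), tx_expr, cfg.min_fpkm
            )
        )
        calls = []
        for tid, intron in ir_pairs:
            if tid not in kept:
                continue
            t = tx_by_id[tid]
            ref = reference_orf(gene_by_id[t.gene_id], genome)
            calls.append(classify_ptc(t, ref, genome, intron))
        return calls

    calls = _ptc()
    write_ptc_table(calls, out("ptc_calls.tsv"))
    census = ptc_census(calls, tx_expr, cfg.min_fpkm)

    # --- splice sites ------------------------------------------------------
    profiles = _stage("splice-sites")(site_proportions)(genes, flags, genome)
    write_profile(profiles, out("splice_sites.tsv"))

    # --- features ----------------------------------------------------------
    records = _stage("features")(feature_table)(genes, events)
    records.to_csv(out("gene_features.tsv"), sep="\t")
    group_summary = compare_groups(records)
    group_summary.to_csv(out("feature_groups.tsv"), sep="\t", index=False)

    @_stage("noncoding")
    def _noncoding():
        as_tx = {tid for ev in events for tid in ev.inclusion | ev.exclusion}
        flagged = []
        for g in genes:
            for t in g.transcripts:
                if t.transcript_id in as_tx and flag_noncoding(t, genome):
                    flagged.append(t.transcript_id)
        return sorted(flagged)

    noncoding_as = _noncoding()

    # --- tissue specificity -------------------------------------------------
    specific = _stage("tissue-specificity")(tissue_specific_sets)(
        events, genes, tx_expr, cfg.min_fpkm, gene_expr
    )

    # --- coexpression -------------------------------------------------------
    @_stage("coexpression")
    def _coexpr():
        expr = gene_expr if gene_expr is not None else tx_expr
        kept = variance_top_fraction(expr, cfg.variance_fraction)
        logged = expr.log_transform().loc[kept]
        return coexpression_analysis(
            logged,
            power=cfg.power,
            min_module_size=cfg.min_module_size,
            hub_fraction=cfg.hub_fraction,
            cut_height=cfg.cut_height,
        )

    coex = _coexpr()
    coex.hubs.to_csv(out("modules.tsv"), sep="\t")

    # --- summary & manifest --------------------------------------------------
    hub_lists = {
        str(m): sorted(coex.hubs.index[(coex.hubs["module"] == m) & coex.hubs["hub"]])
        for m in sorted(set(coex.hubs["module"]))
    }
    summary = {
        "n_genes": len(genes),
        "n_transcripts": sum(len(g.transcripts) for g in genes),
        "as_gene_percent": round(as_pct, 2),
        "n_events": summary_ev.total,
        "event_counts": summary_ev.counts,
        "event_percent": summary_ev.proportions,
        "ptc_plus": census.n_plus,
        "ptc_minus": census.n_minus,
        "ptc_ratio": census.ratio,
        "splice_site_top5": {
            grp: [
                {"donor": d, "acceptor": a, "count": c, "percent": round(p, 2)}
                for (d, a), c, p in profiles[grp].top(5)
            ]
            for grp in ("AS", "non-AS", "all")
        },
        "n_noncoding_as_transcripts": len(noncoding_as),
        "tissue_specific_as_transcripts": {
            t: len(v) for t, v in specific["transcripts"].items()
        },
        "tissue_specific_as_genes": {t: len(v) for t, v in specific["genes"].items()},
        "coexpression_power": coex.power,
        "module_sizes": {
            str(m): int((coex.modules == m).sum()) for m in sorted(coex.modules.unique())
        },
        "hub_genes": hub_lists,
    }
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "tool": "splicescape",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in vars(cfg).items() if not k.startswith("_")
        },
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
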