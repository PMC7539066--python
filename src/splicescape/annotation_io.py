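"""Readers and writers for GTF/GFF3 annotations and FASTA genomes."""

from __future__ import annotations

import os
from typing import Dict, List, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, GenomeSequence, TranscriptModel

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
]


def _validate_lines(path: str) -> None:
    """Cheap structural pass so malformed lines are reported by number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"{path}: malformed annotation line {lineno}: "
                    f"expected >=8 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed annotation line {lineno}: "
                    f"non-integer coordinates"
                ) from exc
            if end < start:
                raise ValueError(
                    f"{path}: malformed annotation line {lineno}: "
                    f"end {end} < start {start}"
                )


def _first(attrs, *keys) -> Optional[str]:
    for k in keys:
        if k in attrs:
            v = attrs[k]
            return v[0] if isinstance(v, (list, tuple)) else v
    return None


def read_annotation(
    path: str, genome: Optional[GenomeSequence] = None
) -> List[GeneModel]:
    """Parse a GTF2.2 or GFF3 file into validated :class:`GeneModel`\\ s.

    Transcripts are reconstructed from exon features; CDS features, when
    present, contribute a genomic CDS span per transcript. Genes are
    returned deterministically ordered by (chromosome, start, gene id).
    When ``genome`` is given, every referenced chromosome must exist and
    every exon must lie within its bounds.
    """
    _validate_lines(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # transcript id -> gene id, resolved from attributes or the GFF3 parent
    # hierarchy (exon -> mRNA -> gene)
    tx_gene: Dict[str, str] = {}
    tx_exons: Dict[str, List[tuple]] = {}
    tx_cds: Dict[str, List[tuple]] = {}
    tx_loc: Dict[str, tuple] = {}

    def resolve_ids(feature) -> tuple:
        tid = _first(feature.attributes, "transcript_id", "Parent")
        gid = _first(feature.attributes, "gene_id")
        if gid is None and tid is not None:
            try:
                parent = db[tid]
                gid = _first(parent.attributes, "gene_id", "Parent")
                if gid is None:
                    gid = parent.id
            except gffutils.FeatureNotFoundError:
                gid = None
        if tid is None or gid is None:
            raise ValueError(
                f"{path}: exon at {feature.seqid}:{feature.start}-{feature.end} "
                f"lacks transcript/gene attributes"
            )
        return tid, gid

    for ftype, store in (("exon", tx_exons), ("CDS", tx_cds)):
        for f in db.features_of_type(ftype):
            tid, gid = resolve_ids(f)
            prev = tx_gene.get(tid)
            if prev is not None and prev != gid:
                raise ValueError(
                    f"{path}: transcript {tid!r} assigned to two genes "
                    f"({prev!r}, {gid!r})"
                )
            tx_gene[tid] = gid
            loc = (f.seqid, f.strand)
            if tid in tx_loc and tx_loc[tid] != loc:
                raise ValueError(
                    f"{path}: transcript {tid!r} spans two chromosomes or strands"
                )
            tx_loc[tid] = loc
            store.setdefault(tid, []).append((f.start, f.end))

    genes: Dict[str, GeneModel] = {}
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for tid in sorted(tx_exons):
        chrom, strand = tx_loc[tid]
        exons = tuple(sorted(tx_exons[tid]))
        cds = None
        if tid in tx_cds:
            pieces = tx_cds[tid]
            cds = (min(s for s, _ in pieces), max(e for _, e in pieces))
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=tx_gene[tid],
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds=cds,
        )
        if genome is not None:
            if chrom not in genome:
                raise ValueError(
                    f"{path}: transcript {tid!r} references unknown "
                    f"chromosome {chrom!r}"
                )
            if t.end > genome.length(chrom):
                raise ValueError(
                    f"{path}: transcript {tid!r} extends beyond {chrom!r} "
                    f"(length {genome.length(chrom)})"
                )
        by_gene.setdefault(tx_gene[tid], []).append(t)

    for gid, txs in by_gene.items():
        chroms = {t.chrom for t in txs}
        strands = {t.strand for t in txs}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"{path}: gene {gid!r} has transcripts on conflicting "
                f"chromosomes or strands"
            )
        genes[gid] = GeneModel(
            gene_id=gid, chrom=txs[0].chrom, strand=txs[0].strand, transcripts=txs
        )

    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def write_annotation(genes: List[GeneModel], path: str, source: str = "splicescape") -> None:
    """Write gene models as GTF2.2 (gene, transcript, exon, CDS features)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in sorted(g.transcripts, key=lambda t: (t.start, t.transcript_id)):
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{t.start}\t{t.end}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )
                if t.cds is not None:
                    cs, ce = t.cds
                    # clip the CDS span to exonic pieces
                    for s, e in t.exons:
                        lo, hi = max(s, cs), min(e, ce)
                        if lo <= hi:
                            fh.write(
                                f"{g.chrom}\t{source}\tCDS\t{lo}\t{hi}\t.\t"
                                f"{g.strand}\t0\t{tattrs}\n"
                            )


def read_fasta(path: str) -> GenomeSequence:
    """Load a plain (optionally unindexed) FASTA file into memory."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if not seqs and os.path.getsize(path) > 0:
        raise ValueError(f"{path}: no FASTA records parsed")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome.sequence(c)), id=c, description="")
        for c in genome.chromosomes()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
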