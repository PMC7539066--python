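import numpy as np
import pandas as pd
import pytest

from splicescape.expression import ExpressionMatrix
from splicescape.models import GeneModel, GenomeSequence, TranscriptModel


def make_tx(tid, exons, gid="G1", chrom="chr1", strand="+", cds=None):
    return TranscriptModel(
        transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
        exons=tuple(exons), cds=cds,
    )


def make_gene(transcripts, gid="G1", chrom="chr1", strand="+"):
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand, transcripts=transcripts)


@pytest.fixture
def ir_gene():
    """Two isoforms: t1 splices the middle intron, t2 retains it."""
    t1 = make_tx("G1.t1", [(101, 200), (301, 400), (501, 600)])
    t2 = make_tx("G1.t2", [(101, 200), (301, 600)])
    return make_gene([t1, t2])


@pytest.fixture
def es_gene():
    """t1 includes the middle exon, t2 skips it with one long intron."""
    t1 = make_tx("G2.t1", [(101, 200), (301, 400), (501, 600)], gid="G2")
    t2 = make_tx("G2.t2", [(101, 200), (501, 600)], gid="G2")
    return make_gene([t1, t2], gid="G2")


@pytest.fixture
def toy_genome():
    """600 bp of A with marked positions for splice-site checks."""
    seq = list("A" * 700)
    # introns of the ir/es fixture genes: (201,300) and (401,500)
    for s, e in [(201, 300), (401, 500)]:
        seq[s - 1 : s + 1] = "GT"
        seq[e - 2 : e] = "AG"
    return GenomeSequence({"chr1": "".join(seq)})


def expr_matrix(rows, tissues=("leaf", "petal"), n_rep=2):
    """Build an ExpressionMatrix from {row_id: {tissue: mean_value}}; all
    replicates of a tissue share the mean so presence is unambiguous."""
    samples = [f"{t}_{r + 1}" for t in tissues for r in range(n_rep)]
    data = {
        rid: [vals.get(s.rsplit("_", 1)[0], 0.0) for s in samples]
        for rid, vals in rows.items()
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return ExpressionMatrix(values=df, tissue_map={s: s.rsplit("_", 1)[0] for s in samples})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
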