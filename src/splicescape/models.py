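"""Strand-aware gene and transcript interval models.

Coordinates follow the GTF convention throughout: 1-based, closed
intervals on the forward genomic strand. Transcript orientation (5'->3'
of the mature RNA) is obtained by reversing the genomic exon order on
the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "GeneModel",
    "Intron",
    "introns_of",
    "spliced_sequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome: a mapping of chromosome id to nucleotide string.

    Lookups are 1-based closed intervals; requests beyond the sequence
    bounds raise ``ValueError`` rather than silently truncating.
    """

    def __init__(self, sequences: Dict[str, str]):
        self._seqs = {str(k): str(v).upper() for k, v in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def chromosomes(self) -> List[str]:
        return sorted(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand slice [start, end], 1-based closed."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start}, {end}] out of bounds for {chrom!r} "
                f"(length {len(seq)})"
            )
        return seq[start - 1 : end]


@dataclass(frozen=True)
class Intron:
    """Closed 1-based interval between two consecutive exons."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"intron end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated isoform: an ordered set of exons plus optional CDS.

    ``exons`` are genomically sorted, non-overlapping closed intervals.
    ``cds`` is the genomic span (leftmost, rightmost) of the coding
    sequence; on the minus strand the start codon anchors at the right
    end of this span.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-'"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e < s:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon end {e} < start {s}"
                )
            if prev_end is not None and s <= prev_end + 1:
                # abutting exons would imply a zero-length intron
                raise ValueError(
                    f"transcript {self.transcript_id}: exons unsorted, "
                    f"overlapping or abutting"
                )
            prev_end = e
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.start <= cs <= ce <= self.end):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS outside transcript span"
                )
            object.__setattr__(self, "cds", (cs, ce))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def exons_tx_order(self) -> Tuple[Tuple[int, int], ...]:
        """Exons in transcript (5'->3') orientation."""
        return self.exons if self.strand == "+" else self.exons[::-1]


@dataclass
class GeneModel:
    """A gene: one or more isoforms sharing chromosome and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: List[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        seen = set()
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValueError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} on a "
                    f"different chromosome or strand"
                )
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} carries "
                    f"gene_id {t.gene_id!r}"
                )
            if t.transcript_id in seen:
                raise ValueError(
                    f"gene {self.gene_id}: duplicate transcript id "
                    f"{t.transcript_id!r}"
                )
            seen.add(t.transcript_id)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


def introns_of(t: TranscriptModel) -> List[Intron]:
    """Introns of a transcript in genomic order: exactly n_exons - 1 of them.

    Intron i spans (exon_i.end + 1, exon_{i+1}.start - 1).
    """
    out = []
    for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
        out.append(Intron(e1 + 1, s2 - 1))
    return out


def spliced_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    """Mature transcript sequence in 5'->3' transcript orientation."""
    seq = "".join(genome.fetch(t.chrom, s, e) for s, e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq
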