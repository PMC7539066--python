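"""Intron-terminal dinucleotide profiling (donor/acceptor splice sites).

For every intron, the first two and last two intron bases are read in
transcript orientation, so the canonical spliceosomal signature appears
as the pair (GT, AG) regardless of strand. Introns are pooled per
transcript by default — an intron shared by two isoforms counts twice —
with a unique-intron mode available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .models import (
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    introns_of,
    reverse_complement,
)

__all__ = [
    "SpliceSiteProfile",
    "terminal_dinucleotides",
    "site_proportions",
    "write_profile",
]

DEGENERATE = ("NN", "NN")


@dataclass
class SpliceSiteProfile:
    """Counts of (donor, acceptor) dinucleotide pairs for one gene group."""

    group: str
    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, pair: Tuple[str, str]) -> None:
        self.counts[pair] = self.counts.get(pair, 0) + 1

    def percentages(self) -> Dict[Tuple[str, str], float]:
        total = self.total
        if total == 0:
            return {}
        return {p: 100.0 * c / total for p, c in self.counts.items()}

    def top(self, k: int = 5) -> List[Tuple[Tuple[str, str], int, float]]:
        """Top-k pairs as (pair, count, percent), ties broken alphabetically."""
        total = self.total
        ranked = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(p, c, 100.0 * c / total) for p, c in ranked[:k]]


def terminal_dinucleotides(
    t: TranscriptModel, genome: GenomeSequence
) -> List[Tuple[str, str]]:
    """(donor, acceptor) dinucleotide per intron, transcript orientation.

    On the minus strand the donor is the genomic-right intron end and
    both dinucleotides are reverse-complemented. Introns shorter than
    4 nt cannot carry two disjoint dinucleotides and are reported under
    the degenerate ("NN", "NN") key.
    """
    pairs: List[Tuple[str, str]] = []
    intr = introns_of(t)
    if t.strand == "-":
        intr = intr[::-1]
    for i in intr:
        if i.length < 4:
            pairs.append(DEGENERATE)
            continue
        left = genome.fetch(t.chrom, i.start, i.start + 1)
        right = genome.fetch(t.chrom, i.end - 1, i.end)
        if t.strand == "+":
            pairs.append((left, right))
        else:
            pairs.append((reverse_complement(right), reverse_complement(left)))
    return pairs


def site_proportions(
    genes: Sequence[GeneModel],
    as_flags: Mapping[str, bool],
    genome: GenomeSequence,
    unique_introns: bool = False,
) -> Dict[str, SpliceSiteProfile]:
    """Splice-site profiles for the AS, non-AS, and pooled gene groups.

    Introns are pooled over all transcripts of each gene in the group;
    with ``unique_introns`` each distinct genomic intron of a gene counts
    once.
    """
    profiles = {
        "AS": SpliceSiteProfile("AS"),
        "non-AS": SpliceSiteProfile("non-AS"),
        "all": SpliceSiteProfile("all"),
    }
    for g in genes:
        group = "AS" if as_flags.get(g.gene_id, False) else "non-AS"
        seen: set = set()
        for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
            dinucs = terminal_dinucleotides(t, genome)
            intr = introns_of(t)
            if t.strand == "-":
                intr = intr[::-1]
            for i, pair in zip(intr, dinucs):
                if unique_introns:
                    key = (i.start, i.end)
                    if key in seen:
                        continue
                    seen.add(key)
                profiles[group].add(pair)
                profiles["all"].add(pair)
    return profiles


def write_profile(profiles: Mapping[str, SpliceSiteProfile], path: str) -> None:
    """TSV export: group, donor, acceptor, count, percent."""
    with open(path, "w") as fh:
        fh.write("group\tdonor\tacceptor\tcount\tpercent\n")
        for name in sorted(profiles):
            prof = profiles[name]
            total = prof.total
            for (d, a), c in sorted(prof.counts.items(), key=lambda kv: (-kv[1], kv[0])):
                pct = 100.0 * c / total if total else 0.0
                fh.write(f"{name}\t{d}\t{a}\t{c}\t{pct:.2f}\n")
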