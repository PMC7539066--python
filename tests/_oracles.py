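"""Independent, deliberately naive reference implementations used as
test oracles. These are coded directly from the event/TOM definitions
with plain loops and no shared helpers, so agreement with the package
implementations is meaningful."""

from typing import Dict, FrozenSet, List, Tuple

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    out = []
    for ch in seq:
        out.append(COMPLEMENT[ch.upper()])
    out.reverse()
    return "".join(out)


def naive_spliced(exons, strand, chrom_seq: str) -> str:
    """Mature sequence from a 1-based chromosome string."""
    s = ""
    for a, b in exons:
        s += chrom_seq[a - 1 : b]
    if strand == "-":
        s = naive_revcomp(s)
    return s


# ---------------------------------------------------------------------------
# brute-force AS event enumeration

Call = Tuple[str, Tuple[int, ...], FrozenSet[str], FrozenSet[str]]


def _adjacent_pairs(exons):
    return [(exons[i], exons[i + 1]) for i in range(len(exons) - 1)]


def _disjoint(e, f) -> bool:
    return e[1] < f[0] or f[1] < e[0]


def brute_force_events(gene) -> List[Call]:
    """All deduplicated events of a gene, as (type, signature, inclusion,
    exclusion) tuples sorted by (type, signature)."""
    acc: Dict[Tuple[str, Tuple[int, ...]], Tuple[set, set]] = {}

    def note(etype, sig, inc, exc):
        key = (etype, tuple(sig))
        if key not in acc:
            acc[key] = (set(), set())
        acc[key][0].update(inc)
        acc[key][1].update(exc)

    strand = gene.strand
    txs = list(gene.transcripts)
    for x in txs:
        for y in txs:
            if x.transcript_id == y.transcript_id:
                continue
            xe, ye = list(x.exons), list(y.exons)

            # IR: adjacent exon pair of x fused into a single y exon
            for (p, q) in _adjacent_pairs(xe):
                for w in ye:
                    if w[0] == p[0] and w[1] == q[1]:
                        note("IR", (p[1], q[0]), [y.transcript_id], [x.transcript_id])

            # ES: internal exon of x absent from y, flanks sharing splice sites
            for j in range(1, len(xe) - 1):
                up, mid, down = xe[j - 1], xe[j], xe[j + 1]
                for (a, b) in _adjacent_pairs(ye):
                    if a[1] == up[1] and b[0] == down[0]:
                        note(
                            "ES",
                            (up[1], mid[0], mid[1], down[0]),
                            [x.transcript_id],
                            [y.transcript_id],
                        )

            # A5 / A3: introns sharing exactly one boundary, with the exons
            # flanking the differing boundary overlapping
            for i, (lx, rx) in enumerate(_adjacent_pairs(xe)):
                intron_x = (lx[1] + 1, rx[0] - 1)
                for k, (ly, ry) in enumerate(_adjacent_pairs(ye)):
                    intron_y = (ly[1] + 1, ry[0] - 1)
                    share_left = intron_x[0] == intron_y[0]
                    share_right = intron_x[1] == intron_y[1]
                    if share_left and share_right:
                        continue
                    if not share_left and not share_right:
                        continue
                    if share_right:
                        # differ at genomic-left edge: left flanks must overlap
                        if _disjoint(lx, ly):
                            continue
                        etype = "A5" if strand == "+" else "A3"
                    else:
                        if _disjoint(rx, ry):
                            continue
                        etype = "A3" if strand == "+" else "A5"
                    sig = tuple(
                        sorted({intron_x[0], intron_x[1], intron_y[0], intron_y[1]})
                    )
                    len_x = intron_x[1] - intron_x[0]
                    len_y = intron_y[1] - intron_y[0]
                    if len_x < len_y:
                        note(etype, sig, [x.transcript_id], [y.transcript_id])
                    else:
                        note(etype, sig, [y.transcript_id], [x.transcript_id])

            # MX: one internal exon each between shared outer splice sites
            for j in range(1, len(xe) - 1):
                for k in range(1, len(ye) - 1):
                    if xe[j - 1][1] != ye[k - 1][1]:
                        continue
                    if xe[j + 1][0] != ye[k + 1][0]:
                        continue
                    if not _disjoint(xe[j], ye[k]):
                        continue
                    ordered = sorted([xe[j], ye[k]])
                    sig = (ordered[0][0], ordered[0][1], ordered[1][0], ordered[1][1])
                    five = ordered[0] if strand == "+" else ordered[1]
                    if xe[j] == five:
                        note("MX", sig, [x.transcript_id], [y.transcript_id])
                    else:
                        note("MX", sig, [y.transcript_id], [x.transcript_id])

            # AF / AL: distinct non-overlapping terminal exons, adjacent
            # introns sharing the internal-side boundary
            if len(xe) >= 2 and len(ye) >= 2:
                for terminal in ("left", "right"):
                    if terminal == "left":
                        tx, anchor_x = xe[0], xe[1][0]
                        ty, anchor_y = ye[0], ye[1][0]
                        etype = "AF" if strand == "+" else "AL"
                    else:
                        tx, anchor_x = xe[-1], xe[-2][1]
                        ty, anchor_y = ye[-1], ye[-2][1]
                        etype = "AL" if strand == "+" else "AF"
                    if anchor_x != anchor_y:
                        continue
                    if tx == ty or not _disjoint(tx, ty):
                        continue
                    ordered = sorted([tx, ty])
                    sig = (ordered[0][0], ordered[0][1], ordered[1][0], ordered[1][1])
                    five = ordered[0] if strand == "+" else ordered[1]
                    if tx == five:
                        note(etype, sig, [x.transcript_id], [y.transcript_id])
                    else:
                        note(etype, sig, [y.transcript_id], [x.transcript_id])

    calls: List[Call] = []
    for (etype, sig), (inc, exc) in acc.items():
        exc = exc - inc  # inclusion role wins a contradiction
        if inc and exc:
            calls.append((etype, sig, frozenset(inc), frozenset(exc)))
    calls.sort(key=lambda c: (c[0], c[1]))
    return calls


def package_events_as_calls(events) -> List[Call]:
    """Normalize package ASEvent objects for comparison with the oracle."""
    calls = [
        (e.event_type, tuple(e.signature), frozenset(e.inclusion), frozenset(e.exclusion))
        for e in events
    ]
    calls.sort(key=lambda c: (c[0], c[1]))
    return calls


# ---------------------------------------------------------------------------
# brute-force topological overlap

def brute_force_tom(a) -> List[List[float]]:
    """TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    computed with explicit loops on a plain list-of-lists matrix."""
    n = len(a)
    k = []
    for i in range(n):
        total = 0.0
        for u in range(n):
            if u != i:
                total += a[i][u]
        k.append(total)
    tom = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i][j] = 1.0
                continue
            shared = 0.0
            for u in range(n):
                if u != i and u != j:
                    shared += a[i][u] * a[u][j]
            tom[i][j] = (shared + a[i][j]) / (min(k[i], k[j]) + 1.0 - a[i][j])
    return tom


def adjusted_rand(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions, from the contingency
    table with plain loops."""
    from math import comb

    a_cats = sorted(set(labels_a))
    b_cats = sorted(set(labels_b))
    table = [[0] * len(b_cats) for _ in a_cats]
    for x, y in zip(labels_a, labels_b):
        table[a_cats.index(x)][b_cats.index(y)] += 1
    sum_ij = sum(comb(v, 2) for row in table for v in row)
    sum_a = sum(comb(sum(row), 2) for row in table)
    sum_b = sum(comb(sum(row[j] for row in table), 2) for j in range(len(b_cats)))
    n_pairs = comb(len(labels_a), 2)
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


# ---------------------------------------------------------------------------
# random gene models for oracle-equivalence sweeps

def random_gene_model(rng, gid: str):
    """A random gene with <=4 transcripts of <=8 exons on a coarse
    coordinate grid (so isoforms coincidentally share boundaries)."""
    from splicescape.models import GeneModel, TranscriptModel

    strand = "+" if rng.random() < 0.5 else "-"

    def chain():
        n = int(rng.integers(1, 9))
        pos = int(rng.integers(1, 11)) * 5
        exons = []
        for _ in range(n):
            length = int(rng.integers(1, 7)) * 5
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(1, 7)) * 5
        return exons

    def mutate(exons):
        exons = [list(e) for e in exons]
        op = rng.integers(0, 5)
        if op == 0 and len(exons) >= 2:  # fuse two adjacent exons
            i = int(rng.integers(0, len(exons) - 1))
            exons[i][1] = exons[i + 1][1]
            del exons[i + 1]
        elif op == 1 and len(exons) >= 3:  # drop an internal exon
            del exons[int(rng.integers(1, len(exons) - 1))]
        elif op == 2:  # shift one exon boundary
            i = int(rng.integers(0, len(exons)))
            side = int(rng.integers(0, 2))
            delta = int(rng.integers(-3, 4)) * 5
            exons[i][side] += delta
        elif op == 3 and len(exons) >= 3:  # relocate an internal exon
            i = int(rng.integers(1, len(exons) - 1))
            length = int(rng.integers(1, 5)) * 5
            start = exons[i - 1][1] + int(rng.integers(1, 5)) * 5
            exons[i] = [start, start + length - 1]
        elif op == 4 and len(exons) >= 2:  # replace a terminal exon
            i = 0 if rng.random() < 0.5 else len(exons) - 1
            length = int(rng.integers(1, 5)) * 5
            if i == 0:
                end = exons[1][0] - int(rng.integers(1, 5)) * 5 - 1
                exons[0] = [end - length + 1, end]
            else:
                start = exons[-2][1] + int(rng.integers(1, 5)) * 5 + 1
                exons[-1] = [start, start + length - 1]
        return [tuple(e) for e in exons]

    base = chain()
    n_tx = int(rng.integers(1, 5))
    transcripts = []
    for t in range(n_tx):
        if t == 0:
            exons = list(base)
        elif rng.random() < 0.25:
            exons = chain()
        else:
            exons = list(base)
            for _ in range(int(rng.integers(1, 3))):
                exons = mutate(exons)
        tid = f"{gid}.t{t + 1}"
        try:
            tx = TranscriptModel(tid, gid, "chrT", strand, tuple(exons))
        except ValueError:  # mutation produced an invalid structure
            tx = TranscriptModel(tid, gid, "chrT", strand, tuple(base))
        transcripts.append(tx)
    # duplicate structures are fine; duplicate ids are not possible here
    return GeneModel(gid, "chrT", strand, transcripts)
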