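"""Greedy assembly of screened reads and paired-end joining of long transcripts.

Assembly is a deterministic greedy maximal-overlap merger (a desk-scale
stand-in for a de Bruijn assembler).  Contigs longer than 200 bases are the
"long transcripts".  Joining then maps all retained pairs back to the long
transcripts; whenever more than ``min_support`` distinct pairs have one end
on transcript a and the other on transcript b, the two are chained.  Chains
("a:b", then "a:b:c" by iteration) are concatenated with an N-gap spacer in
the orientation dictated by the mate strands.  Components with branches or
cycles are never joined: the evidence does not define an order.
"""

from __future__ import annotations

import heapq
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import iter_kmers, revcomp
from .read_screening import ReadPair

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 31
DEFAULT_MIN_LEN = 200
DEFAULT_MIN_SUPPORT = 5
DEFAULT_GAP = 50
DEFAULT_K = 28


@dataclass
class Transcript:
    """An assembled (or joined) transcript."""

    id: str
    seq: str
    members: list[str] = field(default_factory=list)
    member_seqs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            self.members = [self.id]
        if not self.member_seqs:
            self.member_seqs = [self.seq]

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class LinkRecord:
    """One read pair bridging two different transcripts."""

    pair_id: str
    transcript_a: str
    transcript_b: str
    end_a: str  # '5p' | '3p' — which end of a the mate sits near
    end_b: str
    strand_a: str  # '+' | '-' — mapped strand of the mate on a
    strand_b: str


@dataclass
class JoinEdge:
    support: int
    side_a: str  # attachment end of the lexicographically smaller node
    side_b: str


@dataclass
class JoinGraph:
    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], JoinEdge] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Greedy overlap assembly
# ---------------------------------------------------------------------------

def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    """Largest k >= min_overlap with a[-k:] == b[:k] and b extending past a; else 0."""
    seed = b[:min_overlap]
    p = a.find(seed)
    while p != -1:
        k = len(a) - p
        if k >= min_overlap and len(b) > k and a.endswith(b[:k]):
            return k
        p = a.find(seed, p + 1)
    return 0


def greedy_assemble(
    pairs: Iterable[ReadPair],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
    id_prefix: str = "asm|",
) -> list[Transcript]:
    """Merge reads by maximal exact suffix-prefix overlap; keep contigs > min_len.

    Both orientations of every read enter the pool; the final contig set is
    deduplicated to canonical strand.  Deterministic: reads are canonically
    ordered lexicographically and overlap ties break lexicographically.
    """
    if min_overlap < 16:
        raise ValueError("min_overlap must be >= 16")
    pool: set[str] = set()
    for p in pairs:
        for s in (p.seq1, p.seq2):
            pool.add(s)
            pool.add(revcomp(s))
    # containment removal (substrings add no information to the merger)
    ordered = sorted(pool, key=len, reverse=True)
    kept: list[str] = []
    for s in ordered:
        if not any(s in t for t in kept):
            kept.append(s)
    contigs: dict[int, str] = {i: s for i, s in enumerate(sorted(kept))}

    heap: list[tuple[int, str, str, int, int]] = []

    def push_overlaps(i: int, js: Iterable[int]) -> None:
        a = contigs[i]
        for j in js:
            if j == i or j not in contigs:
                continue
            b = contigs[j]
            k = _best_overlap(a, b, min_overlap)
            if k:
                heapq.heappush(heap, (-k, a, b, i, j))

    ids = list(contigs)
    for i in ids:
        push_overlaps(i, ids)
    next_id = len(contigs)
    while heap:
        negk, a, b, i, j = heapq.heappop(heap)
        if i not in contigs or j not in contigs or contigs[i] != a or contigs[j] != b:
            continue  # stale entry
        k = -negk
        merged = a + b[k:]
        # consume the two merged contigs; their reverse complements stay in
        # the pool so the mirror-orientation assembly can proceed in parallel
        # (the final canonical dedupe collapses the two strands)
        del contigs[i], contigs[j]
        # drop anything now contained in the merged contig (same orientation)
        for key in [key for key, s in contigs.items() if s in merged]:
            del contigs[key]
        contigs[next_id] = merged
        push_overlaps(next_id, list(contigs))
        for i2 in list(contigs):
            if i2 != next_id:
                a2 = contigs[i2]
                k2 = _best_overlap(a2, merged, min_overlap)
                if k2:
                    heapq.heappush(heap, (-k2, a2, merged, i2, next_id))
        next_id += 1

    finals: set[str] = set()
    for s in contigs.values():
        if len(s) > min_len:
            finals.add(min(s, revcomp(s)))
    # remove contigs contained in longer contigs (either strand)
    out_seqs: list[str] = []
    for s in sorted(finals, key=lambda x: (-len(x), x)):
        if not any(s in t or revcomp(s) in t for t in out_seqs):
            out_seqs.append(s)
    out_seqs.sort()
    return [Transcript(id=f"{id_prefix}{n + 1}", seq=s) for n, s in enumerate(out_seqs)]


# ---------------------------------------------------------------------------
# Read placement on transcripts (exact-seed mapping)
# ---------------------------------------------------------------------------

class TranscriptIndex:
    """Exact k-mer positional index over a transcript set (forward strand)."""

    def __init__(self, transcripts: Sequence[Transcript], k: int = DEFAULT_K):
        self.k = k
        self.lengths = {t.id: len(t.seq) for t in transcripts}
        self.kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for t in transcripts:
            for i in range(len(t.seq) - k + 1):
                km = t.seq[i : i + k]
                if "N" not in km:
                    self.kmers[km].append((t.id, i))

    def place(self, seq: str) -> tuple[str, str, int, int] | None:
        """Unique best exact-seed placement of a read.

        Returns (transcript_id, strand, start, score) where score is the
        number of seed k-mers supporting the best diagonal.  None when the
        read has no hits or maps equally well to more than one transcript.
        """
        scores: Counter[tuple[str, str, int]] = Counter()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for off in range(len(s) - self.k + 1):
                km = s[off : off + self.k]
                if "N" in km:
                    continue
                for tid, pos in self.kmers.get(km, ()):
                    scores[(tid, strand, pos - off)] += 1
        if not scores:
            return None
        best = max(scores.values())
        top = sorted(key for key, v in scores.items() if v == best)
        if len({key[0] for key in top}) > 1:
            return None  # ambiguous across transcripts
        tid, strand, start = top[0]
        return tid, strand, start, best


def map_pairs_to_transcripts(
    pairs: Iterable[ReadPair],
    transcripts: Sequence[Transcript],
    k: int = DEFAULT_K,
) -> list[LinkRecord]:
    """Emit a link for every pair whose mates place uniquely on two transcripts."""
    if not transcripts:
        raise ValueError("map_pairs_to_transcripts requires transcripts")
    index = TranscriptIndex(transcripts, k=k)
    links: list[LinkRecord] = []
    skipped_ambiguous = 0
    for p in pairs:
        pl1 = index.place(p.seq1)
        pl2 = index.place(p.seq2)
        if pl1 is None or pl2 is None:
            skipped_ambiguous += 1
            continue
        t1, strand1, start1, _ = pl1
        t2, strand2, start2, _ = pl2

        def end_of(tid: str, start: int, read_len: int) -> str:
            mid = start + read_len / 2
            return "3p" if mid > index.lengths[tid] / 2 else "5p"

        if t1 == t2:
            continue
        links.append(
            LinkRecord(
                pair_id=p.pair_id,
                transcript_a=t1,
                transcript_b=t2,
                end_a=end_of(t1, start1, len(p.seq1)),
                end_b=end_of(t2, start2, len(p.seq2)),
                strand_a=strand1,
                strand_b=strand2,
            )
        )
    if skipped_ambiguous:
        logger.info("%d mates skipped as unplaced/ambiguous", skipped_ambiguous)
    return links


# ---------------------------------------------------------------------------
# Join graph and chaining
# ---------------------------------------------------------------------------

def _attachment_side(strand: str) -> str:
    """The partner transcript lies off the mate's 3' direction.

    A mate mapped '+' points past the transcript's 3' end; '-' points past
    the 5' end.
    """
    return "3p" if strand == "+" else "5p"


def build_join_graph(links: Iterable[LinkRecord], min_support: int = DEFAULT_MIN_SUPPORT) -> JoinGraph:
    """Edge (a, b) iff *more than* ``min_support`` distinct pairs bridge a and b.

    The consensus attachment sides are the majority over supporting links;
    an orientation tie drops the edge (logged) — the evidence contradicts itself.
    """
    if min_support < 0:
        raise ValueError("min_support must be >= 0")
    by_edge: dict[tuple[str, str], dict[str, tuple[str, str]]] = defaultdict(dict)
    for ln in links:
        if ln.transcript_a == ln.transcript_b:
            continue
        a, b = sorted((ln.transcript_a, ln.transcript_b))
        if a == ln.transcript_a:
            sides = (_attachment_side(ln.strand_a), _attachment_side(ln.strand_b))
        else:
            sides = (_attachment_side(ln.strand_b), _attachment_side(ln.strand_a))
        by_edge[(a, b)].setdefault(ln.pair_id, sides)  # distinct pairs only
    graph = JoinGraph()
    for (a, b), per_pair in sorted(by_edge.items()):
        support = len(per_pair)
        if support <= min_support:
            continue
        counts = Counter(per_pair.values())
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            logger.warning("edge %s-%s dropped: orientation tie (%s)", a, b, dict(counts))
            continue
        sides = ranked[0][0]
        graph.nodes.update((a, b))
        graph.edges[(a, b)] = JoinEdge(support=support, side_a=sides[0], side_b=sides[1])
    return graph


def _components(graph: JoinGraph) -> list[list[str]]:
    adj: dict[str, list[str]] = defaultdict(list)
    for a, b in graph.edges:
        adj[a].append(b)
        adj[b].append(a)
    seen: set[str] = set()
    comps = []
    for node in sorted(graph.nodes):
        if node in seen:
            continue
        comp, stack = [], [node]
        seen.add(node)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def join_transcripts(
    graph: JoinGraph,
    transcripts: Sequence[Transcript],
    gap: int = DEFAULT_GAP,
) -> list[Transcript]:
    """Concatenate simple-path components in evidence order, with an N-gap spacer.

    Components containing a branch (degree > 2) or a cycle are left unjoined
    and logged; mate evidence only ever defines a chain.  Applying the join to
    its own output with a graph rebuilt from the same links is a fixed point.
    """
    by_id = {t.id: t for t in transcripts}
    unknown = graph.nodes - set(by_id)
    if unknown:
        raise ValueError(f"graph references unknown transcripts: {sorted(unknown)}")
    adj: dict[str, list[tuple[str, JoinEdge, bool]]] = defaultdict(list)
    for (a, b), e in graph.edges.items():
        adj[a].append((b, e, True))   # True: this node is the edge's 'a' side
        adj[b].append((a, e, False))

    joined: list[Transcript] = []
    consumed: set[str] = set()
    n_joined = 0
    for comp in _components(graph):
        if len(comp) < 2:
            continue
        degs = {u: len(adj[u]) for u in comp}
        n_edges = sum(degs.values()) // 2
        endpoints = sorted(u for u, d in degs.items() if d == 1)
        if max(degs.values()) > 2 or n_edges != len(comp) - 1 or len(endpoints) != 2:
            logger.warning("component %s left unjoined (branch or cycle)", comp)
            continue
        start = endpoints[0]
        # walk the path, orienting each member so chains run head to tail
        order: list[tuple[str, str]] = []
        prev, cur = None, start
        ok = True
        while True:
            nxt = [(v, e, is_a) for v, e, is_a in adj[cur] if v != prev]
            if not nxt:
                # terminal node: orientation from the edge we arrived by
                break
            v, e, cur_is_a = nxt[0]
            side_cur = e.side_a if cur_is_a else e.side_b
            side_next = e.side_b if cur_is_a else e.side_a
            if prev is None:
                order.append((cur, "+" if side_cur == "3p" else "-"))
            else:
                # interior: the outgoing edge must leave by the trailing end
                trailing = "3p" if order[-1][1] == "+" else "5p"
                if side_cur != trailing:
                    ok = False
                    break
            order.append((v, "+" if side_next == "5p" else "-"))
            prev, cur = cur, v
        if not ok or len(order) != len(comp):
            logger.warning("component %s left unjoined (inconsistent orientations)", comp)
            continue
        n_joined += 1
        member_seqs = [
            by_id[m].seq if o == "+" else revcomp(by_id[m].seq) for m, o in order
        ]
        joined.append(
            Transcript(
                id=f"join|{n_joined}",
                seq=("N" * gap).join(member_seqs),
                members=[m for m, _ in order],
                member_seqs=member_seqs,
            )
        )
        consumed.update(m for m, _ in order)
    out = [t for t in transcripts if t.id not in consumed]
    out.extend(joined)
    return out


def validate_joins(
    joined: Iterable[Transcript],
    truth_seqs: Mapping[str, str],
    max_gap: int = 100,
) -> float:
    """Fraction of multi-member joins whose members tile one planted transcript.

    A join is correct iff its oriented member sequences occur in order, with
    gaps of at most ``max_gap`` bases, within a single planted sequence (or
    its reverse complement).  With no joins the fraction is defined as 1.0.
    """

    def tiles(members: Sequence[str], target: str) -> bool:
        p = target.find(members[0])
        while p != -1:
            pos, ok = p + len(members[0]), True
            for m in members[1:]:
                q = target.find(m, pos)
                if q == -1 or q - pos > max_gap:
                    ok = False
                    break
                pos = q + len(m)
            if ok:
                return True
            p = target.find(members[0], p + 1)
        return False

    multi = [t for t in joined if len(t.members) > 1]
    if not multi:
        logger.info("validate_joins: no multi-member joins; returning 1.0")
        return 1.0
    correct = 0
    for t in multi:
        ms = t.member_seqs
        if any(
            tiles(ms, target) or tiles([revcomp(m) for m in reversed(ms)], target)
            for target in truth_seqs.values()
        ):
            correct += 1
    return correct / len(multi)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_transcripts_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(t.seq), id=t.id, description="members=" + ",".join(t.members))
        for t in transcripts
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_transcripts_fasta(path: str | Path) -> list[Transcript]:
    out = []
    for r in SeqIO.parse(str(path), "fasta"):
        out.append(Transcript(id=r.id, seq=str(r.seq).upper()))
    return out


def write_links_tsv(links: Iterable[LinkRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\ttranscript_a\ttranscript_b\tend_a\tend_b\tstrand_a\tstrand_b\n")
        for ln in links:
            fh.write(
                f"{ln.pair_id}\t{ln.transcript_a}\t{ln.transcript_b}\t"
                f"{ln.end_a}\t{ln.end_b}\t{ln.strand_a}\t{ln.strand_b}\n"
            )
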