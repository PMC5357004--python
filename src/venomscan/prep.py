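"""Read cleaning, greedy assembly and contig quantification.

Stages mirror a venom-gland transcriptome preparation: ribosomal-RNA removal
by similarity to reference rRNA, exact duplicate removal, carry-over
decontamination against a previous sequencing run, greedy exact-overlap
assembly with majority-vote consensus polishing, exact-substring read
mapping for support counting, and RPKM quantification.

The assembler is a deliberate stand-in for a production de novo assembler:
it merges reads on exact suffix-prefix overlaps (both orientations,
processed in descending length then lexicographic order) and then polishes
each contig by majority vote over anchored reads, which is sufficient for
the synthetic, substitution-error-only data this package generates.  Real
contigs can be supplied directly, bypassing this stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib

logger = logging.getLogger(__name__)

__all__ = [
    "Read",
    "Contig",
    "revcomp",
    "remove_rrna",
    "dedup_identical",
    "remove_carryover",
    "assemble",
    "map_support",
    "rpkm",
    "compute_rpkm",
    "filter_support",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class Read:
    """A single sequencing read."""

    id: str
    seq: str
    qual: Optional[str] = None
    run_id: str = "run1"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id} has empty sequence")
        if set(self.seq) - set("ACGTN"):
            raise ValueError(f"read {self.id} has non-ACGTN characters")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id}: quality/sequence length mismatch")


@dataclass
class Contig:
    """An assembled (or supplied) contig with its read support and RPKM."""

    id: str
    seq: str
    read_support: int = 0
    rpkm: float = 0.0

    @property
    def length(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# Filtering stages
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def remove_rrna(reads: Sequence[Read], rrna_refs: Sequence, min_identity: float = 0.90,
                min_cov: float = 0.80, prescreen_k: int = 12) -> List[Read]:
    """Drop reads matching an rRNA reference at >= ``min_identity`` over the read.

    A shared ``prescreen_k``-mer triggers a banded edit-distance alignment
    (infix mode: the whole read against the reference, so coverage of the
    read is complete whenever an alignment exists).  ``min_cov`` is retained
    for API symmetry with local aligners; the infix alignment always spans
    the full read.  Order is preserved.
    """
    if not reads:
        return []
    ref_seqs = [getattr(r, "seq", r) for r in rrna_refs]
    if not ref_seqs:
        raise ValueError("rrna_refs must be non-empty")
    screen = set()
    for ref in ref_seqs:
        screen |= _kmer_set(ref, prescreen_k)
        screen |= _kmer_set(revcomp(ref), prescreen_k)

    kept: List[Read] = []
    removed = 0
    for read in reads:
        hit = False
        if any(read.seq[i:i + prescreen_k] in screen
               for i in range(0, len(read.seq) - prescreen_k + 1)):
            max_dist = int(len(read.seq) * (1.0 - min_identity))
            for ref in ref_seqs:
                for query in (read.seq, revcomp(read.seq)):
                    res = edlib.align(query, ref, mode="HW", task="distance",
                                      k=max_dist)
                    if res["editDistance"] != -1:
                        hit = True
                        break
                if hit:
                    break
        if hit:
            removed += 1
        else:
            kept.append(read)
    logger.info("remove_rrna: kept %d, removed %d", len(kept), removed)
    return kept


def dedup_identical(reads: Sequence[Read]) -> List[Read]:
    """Keep the first occurrence of each identical read sequence."""
    seen = set()
    kept = []
    for read in reads:
        if read.seq not in seen:
            seen.add(read.seq)
            kept.append(read)
    logger.info("dedup_identical: kept %d, removed %d",
                len(kept), len(reads) - len(kept))
    return kept


def remove_carryover(reads: Sequence[Read], prior_run_reads: Sequence[Read]
                     ) -> List[Read]:
    """Drop reads identical (either strand) to any read of a previous run."""
    prior = {r.seq for r in prior_run_reads}
    kept = [r for r in reads if r.seq not in prior and revcomp(r.seq) not in prior]
    logger.info("remove_carryover: kept %d, removed %d",
                len(kept), len(reads) - len(kept))
    return kept


# ---------------------------------------------------------------------------
# Greedy exact-overlap assembly
# ---------------------------------------------------------------------------

def _greedy_merge(seqs: List[str], min_overlap: int) -> List[str]:
    """Greedy superstring chaining on exact suffix-prefix overlaps.

    Each input sequence participates in one orientation only (whichever a
    chain first recruits).  Contained sequences are absorbed up front.
    Deterministic: longer overlaps first, ties by fragment index.
    """
    n = len(seqs)
    oriented: List[str] = []       # 2*i forward, 2*i+1 reverse complement
    for s in seqs:
        oriented.append(s)
        oriented.append(revcomp(s))

    # Absorb fragments exactly contained in a longer (or equal, later) one.
    alive = [True] * n
    index: Dict[str, List[int]] = {}
    for i in range(n):
        index.setdefault(seqs[i][:min_overlap], []).append(i)
        index.setdefault(oriented[2 * i + 1][:min_overlap], []).append(i)
    order = sorted(range(n), key=lambda i: (-len(seqs[i]), seqs[i]))
    rank = {i: pos for pos, i in enumerate(order)}
    for i in order:
        if not alive[i]:
            continue
        for host_ori in (seqs[i], oriented[2 * i + 1]):
            for p in range(len(host_ori) - min_overlap + 1):
                for j in index.get(host_ori[p:p + min_overlap], ()):
                    if j == i or not alive[j]:
                        continue
                    if len(seqs[j]) > len(host_ori) - p:
                        continue
                    frag = seqs[j]
                    if host_ori.startswith(frag, p) or \
                            host_ori.startswith(revcomp(frag), p):
                        if len(frag) < len(seqs[i]) or rank[j] > rank[i]:
                            alive[j] = False

    live = [i for i in order if alive[i]]
    # Candidate suffix->prefix overlap edges among oriented fragments.
    pref: Dict[str, List[int]] = {}
    for i in live:
        for node in (2 * i, 2 * i + 1):
            pref.setdefault(oriented[node][:min_overlap], []).append(node)
    edges: List[Tuple[int, int, int]] = []  # (overlap, src_node, dst_node)
    for i in live:
        for node in (2 * i, 2 * i + 1):
            s = oriented[node]
            for p in range(1, len(s) - min_overlap + 1):
                for dst in pref.get(s[p:p + min_overlap], ()):
                    if dst // 2 == i:
                        continue
                    ov = len(s) - p
                    t = oriented[dst]
                    if ov <= len(t) and s.endswith(t[:ov]):
                        edges.append((ov, node, dst))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))

    nxt: Dict[int, Tuple[int, int]] = {}   # node -> (next node, overlap)
    prv: Dict[int, int] = {}
    orient: Dict[int, int] = {}            # fragment -> chosen node
    parent: Dict[int, int] = {}

    def find(x: int) -> int:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def compatible(node: int) -> bool:
        chosen = orient.get(node // 2)
        return chosen is None or chosen == node

    for ov, a, b in edges:
        if a in nxt or b in prv:
            continue
        if not (compatible(a) and compatible(b)):
            continue
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        nxt[a] = (b, ov)
        prv[b] = a
        parent[ra] = rb
        orient[a // 2] = a
        orient[b // 2] = b

    contigs: List[str] = []
    emitted = set()
    for i in live:
        node = orient.get(i, 2 * i)
        if node in prv or i in emitted:
            continue
        parts = [oriented[node]]
        emitted.add(node // 2)
        while node in nxt:
            node, ov = nxt[node]
            parts.append(oriented[node][ov:])
            emitted.add(node // 2)
        contigs.append("".join(parts))
    return contigs


def _polish(contig: str, reads: Sequence[Read], k: int = 21) -> str:
    """Majority-vote consensus over reads anchored to the contig by exact k-mers.

    Substitution errors only: a read is placed at a single ungapped offset
    via its first error-free k-mer; each placed read votes per position.
    """
    if len(contig) < k:
        return contig
    kindex: Dict[str, int] = {}
    for p in range(len(contig) - k + 1):
        kindex.setdefault(contig[p:p + k], p)
    votes: List[Dict[str, int]] = [dict() for _ in contig]
    for read in reads:
        for seq in (read.seq, revcomp(read.seq)):
            placed = False
            for q in range(0, max(1, len(seq) - k + 1), k):
                p = kindex.get(seq[q:q + k])
                if p is None:
                    continue
                off = p - q
                for j, base in enumerate(seq):
                    pos = off + j
                    if 0 <= pos < len(contig):
                        votes[pos][base] = votes[pos].get(base, 0) + 1
                placed = True
                break
            if placed:
                break
    out = []
    for pos, base in enumerate(contig):
        tally = votes[pos]
        if tally:
            best = max(tally.items(), key=lambda kv: (kv[1], kv[0] == base, kv[0]))
            out.append(best[0])
        else:
            out.append(base)
    return "".join(out)


def assemble(reads: Sequence[Read], min_overlap: int = 40,
             polish: bool = True) -> List[Contig]:
    """Greedy exact-overlap assembly of (error-light) reads into contigs.

    Fragments are processed in descending length then lexicographic order;
    chains form on exact suffix-prefix overlaps >= ``min_overlap`` in either
    orientation.  With ``polish`` (default), each contig is corrected by
    per-position majority vote of the anchored input reads and contigs
    contained in a longer contig (either strand) are dropped.
    """
    if not reads:
        return []
    seqs = sorted({r.seq for r in reads}, key=lambda s: (-len(s), s))
    merged = _greedy_merge(seqs, min_overlap)
    if polish:
        merged = [_polish(c, reads) for c in merged]
        uniq: List[str] = []
        for c in sorted(set(merged), key=lambda s: (-len(s), s)):
            rc = revcomp(c)
            if not any(c in u or rc in u for u in uniq):
                uniq.append(c)
        merged = uniq
    else:
        merged = sorted(merged, key=lambda s: (-len(s), s))
    return [Contig(id=f"contig{i + 1}", seq=s) for i, s in enumerate(merged)]


# ---------------------------------------------------------------------------
# Support counting and RPKM
# ---------------------------------------------------------------------------

def map_support(contigs: Sequence[Contig], reads: Sequence[Read], k: int = 21
                ) -> Tuple[Dict[str, int], int]:
    """Count reads mapping to each contig; a read maps iff it is an exact
    substring (either strand).  Ties go to the longest contig, then the
    lexicographically smallest id; each read counts at most once.

    Returns ``(per-contig counts, total mapped N)`` and updates
    ``contig.read_support`` in place.
    """
    counts: Dict[str, int] = {c.id: 0 for c in contigs}
    if not contigs:
        return counts, 0
    k = min(k, min((len(r.seq) for r in reads), default=k))
    kindex: Dict[str, set] = {}
    for c in contigs:
        for seq in (c.seq, revcomp(c.seq)):
            for p in range(len(seq) - k + 1):
                kindex.setdefault(seq[p:p + k], set()).add(c.id)
    by_id = {c.id: c for c in contigs}
    total = 0
    for read in reads:
        cands = kindex.get(read.seq[:k])
        if not cands:
            continue
        hits = [cid for cid in cands
                if read.seq in by_id[cid].seq or revcomp(read.seq) in by_id[cid].seq]
        if not hits:
            continue
        best = min(hits, key=lambda cid: (-len(by_id[cid].seq), cid))
        counts[best] += 1
        total += 1
    for c in contigs:
        c.read_support = counts[c.id]
    return counts, total


def rpkm(c_i: int, l_i: int, n: int) -> float:
    """Reads per kilobase of contig per million mapped reads: 1e9 * C / (N * L)."""
    if n <= 0:
        raise ValueError("total mapped reads N must be positive")
    if l_i <= 0:
        raise ValueError("contig length must be positive")
    return 1e9 * c_i / (n * l_i)


def compute_rpkm(contigs: Sequence[Contig], total_mapped: int) -> None:
    for c in contigs:
        c.rpkm = rpkm(c.read_support, c.length, total_mapped)


def filter_support(contigs: Sequence[Contig], min_reads: int = 10) -> List[Contig]:
    """Keep contigs with read support >= ``min_reads`` (boundary kept)."""
    kept = [c for c in contigs if c.read_support >= min_reads]
    logger.info("filter_support: kept %d, removed %d",
                len(kept), len(contigs) - len(kept))
    return kept
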