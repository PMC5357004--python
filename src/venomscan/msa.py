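"""Pairwise and progressive multiple alignment of peptide clusters.

A deliberately small, fully deterministic progressive aligner: affine-gap
Gotoh dynamic programming on profile columns (average-of-pairs BLOSUM62
scoring) over a UPGMA guide tree built from pairwise global alignment
scores.  Gap costs follow the convention that a gap run of length *g* costs
``|gap_open| + (g - 1) * |gap_extend|`` (the opening charge covers the first
gapped column), matching Biopython's ``open_gap_score`` / ``extend_gap_score``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from Bio.Align import substitution_matrices

__all__ = ["Msa", "BLOSUM62", "align_pair", "align_cluster", "local_identity"]

GAP = "-"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class Msa:
    """A multiple sequence alignment: (id, aligned row) pairs of equal width."""

    rows: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        widths = {len(r) for _, r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"MSA rows have unequal widths: {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def ungapped(self) -> List[Tuple[str, str]]:
        return [(rid, row.replace(GAP, "")) for rid, row in self.rows]

    def column(self, j: int) -> str:
        return "".join(row[j] for _, row in self.rows)


def _subst(a: str, b: str) -> float:
    return float(BLOSUM62[a][b])


def _column_score(col_a: str, col_b: str) -> float:
    """Average BLOSUM62 score over all residue pairs; gap pairs contribute 0."""
    total = 0.0
    for x in col_a:
        if x == GAP:
            continue
        for y in col_b:
            if y != GAP:
                total += _subst(x, y)
    return total / (len(col_a) * len(col_b))


def _gotoh_columns(cols_a: List[str], cols_b: List[str], gap_open: float,
                   gap_extend: float) -> Tuple[float, List[Tuple[int, int]]]:
    """Global affine alignment of two column lists.

    Returns the score and a traceback as (di, dj) moves: (1,1) aligned
    columns, (1,0) column of A against gap, (0,1) column of B against gap.
    Ties prefer diagonal, then consuming A.
    """
    n, m = len(cols_a), len(cols_b)
    neg = float("-inf")
    open_cost, ext_cost = -abs(gap_open), -abs(gap_extend)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in B (consume A)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in A (consume B)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_cost + (i - 1) * ext_cost
    for j in range(1, m + 1):
        Y[0][j] = open_cost + (j - 1) * ext_cost
    S = [[0.0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            S[i][j] = _column_score(cols_a[i], cols_b[j])
    for j in range(1, m + 1):
        Y[0][j] = open_cost + (j - 1) * ext_cost  # consistent with init above
    for i in range(1, n + 1):
        X[i][0] = open_cost + (i - 1) * ext_cost
        for j in range(1, m + 1):
            M[i][j] = S[i - 1][j - 1] + max(M[i - 1][j - 1], X[i - 1][j - 1],
                                            Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + open_cost, X[i - 1][j] + ext_cost,
                          Y[i - 1][j] + open_cost)
            Y[i][j] = max(M[i][j - 1] + open_cost, Y[i][j - 1] + ext_cost,
                          X[i][j - 1] + open_cost)

    score = max(M[n][m], X[n][m], Y[n][m])
    moves: List[Tuple[int, int]] = []
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i][j])
    # Deterministic preference at ties: M, then X, then Y.
    for cand in ("M", "X", "Y"):
        if {"M": M, "X": X, "Y": Y}[cand][i][j] == score:
            state = cand
            break
    while i > 0 or j > 0:
        if state == "M":
            moves.append((1, 1))
            target = M[i][j] - S[i - 1][j - 1]
            i, j = i - 1, j - 1
            for cand in ("M", "X", "Y"):
                if abs({"M": M, "X": X, "Y": Y}[cand][i][j] - target) < 1e-9:
                    state = cand
                    break
        elif state == "X":
            moves.append((1, 0))
            val = X[i][j]
            i -= 1
            if abs(M[i][j] + open_cost - val) < 1e-9:
                state = "M"
            elif abs(X[i][j] + ext_cost - val) < 1e-9:
                state = "X"
            else:
                state = "Y"
        else:
            moves.append((0, 1))
            val = Y[i][j]
            j -= 1
            if abs(M[i][j] + open_cost - val) < 1e-9:
                state = "M"
            elif abs(Y[i][j] + ext_cost - val) < 1e-9:
                state = "Y"
            else:
                state = "X"
    moves.reverse()
    return score, moves


def _merge(msa_a: Msa, msa_b: Msa, gap_open: float, gap_extend: float) -> Msa:
    cols_a = [msa_a.column(j) for j in range(msa_a.width)]
    cols_b = [msa_b.column(j) for j in range(msa_b.width)]
    _, moves = _gotoh_columns(cols_a, cols_b, gap_open, gap_extend)
    new_a = ["" for _ in msa_a.rows]
    new_b = ["" for _ in msa_b.rows]
    ia = ib = 0
    for di, dj in moves:
        for r in range(len(new_a)):
            new_a[r] += msa_a.rows[r][1][ia] if di else GAP
        for r in range(len(new_b)):
            new_b[r] += msa_b.rows[r][1][ib] if dj else GAP
        ia += di
        ib += dj
    rows = [(msa_a.rows[r][0], new_a[r]) for r in range(len(new_a))]
    rows += [(msa_b.rows[r][0], new_b[r]) for r in range(len(new_b))]
    return Msa(rows)


def align_pair(seq_a: str, seq_b: str, gap_open: float = -10.0,
               gap_extend: float = -1.0) -> Tuple[float, str, str]:
    """Global affine-gap alignment of two peptides under BLOSUM62."""
    score, moves = _gotoh_columns(list(seq_a), list(seq_b), gap_open, gap_extend)
    out_a, out_b = [], []
    ia = ib = 0
    for di, dj in moves:
        out_a.append(seq_a[ia] if di else GAP)
        out_b.append(seq_b[ib] if dj else GAP)
        ia += di
        ib += dj
    return score, "".join(out_a), "".join(out_b)


def align_cluster(seqs: Sequence[Tuple[str, str]], gap_open: float = -10.0,
                  gap_extend: float = -1.0) -> Msa:
    """Progressive alignment of a cluster over a UPGMA guide tree.

    The guide tree uses pairwise global alignment scores (higher score =
    closer); ties are broken lexicographically by the smallest member id of
    each subtree, making the result deterministic.
    """
    if not seqs:
        raise ValueError("cannot align an empty cluster")
    if len(seqs) == 1:
        rid, s = seqs[0]
        return Msa([(rid, s)])

    # Pairwise similarity.
    n = len(seqs)
    sim: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            score, _, _ = align_pair(seqs[i][1], seqs[j][1], gap_open, gap_extend)
            sim[(i, j)] = score

    # UPGMA (average linkage on similarity, merging the most similar pair).
    clusters: Dict[int, List[int]] = {i: [i] for i in range(n)}
    msas: Dict[int, Msa] = {i: Msa([seqs[i]]) for i in range(n)}
    key_of = {i: seqs[i][0] for i in range(n)}
    next_id = n

    def pair_sim(a: int, b: int) -> float:
        total = 0.0
        for x in clusters[a]:
            for y in clusters[b]:
                total += sim[(min(x, y), max(x, y))]
        return total / (len(clusters[a]) * len(clusters[b]))

    while len(clusters) > 1:
        ids = sorted(clusters, key=lambda c: key_of[c])
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                s = pair_sim(a, b)
                cand = (-s, key_of[a], key_of[b])
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        _, a, b = best
        msas[next_id] = _merge(msas[a], msas[b], gap_open, gap_extend)
        clusters[next_id] = clusters[a] + clusters[b]
        key_of[next_id] = min(key_of[a], key_of[b])
        for dead in (a, b):
            del clusters[dead], msas[dead], key_of[dead]
        next_id += 1

    return msas[next_id - 1]


def local_identity(seq_a: str, seq_b: str, gap_open: float = -11.0,
                   gap_extend: float = -1.0) -> Tuple[float, float, float]:
    """Best local alignment of two peptides: (score, identity, shorter-seq coverage).

    Identity is matches / alignment columns; coverage is the aligned span of
    the shorter sequence divided by its length.  Uses Biopython's pairwise
    aligner in local mode under BLOSUM62.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return 0.0, 0.0, 0.0
    aln = aligner.align(seq_a, seq_b)[0]
    a_blocks, b_blocks = aln.aligned
    matches = 0
    columns = 0
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        if prev_a_end is not None:
            columns += (a0 - prev_a_end) + (b0 - prev_b_end)
        for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]):
            columns += 1
            if x == y:
                matches += 1
        prev_a_end, prev_b_end = a1, b1
    identity = matches / columns if columns else 0.0
    span_a = a_blocks[-1][1] - a_blocks[0][0]
    span_b = b_blocks[-1][1] - b_blocks[0][0]
    if len(seq_a) <= len(seq_b):
        shorter, span = len(seq_a), span_a
    else:
        shorter, span = len(seq_b), span_b
    coverage = span / shorter if shorter else 0.0
    return float(score), identity, coverage
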