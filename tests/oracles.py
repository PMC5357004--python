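"""Independent oracles used by the test suite.

Deliberately separate implementations: exhaustive path enumeration for the
profile Viterbi, a plain local Gotoh dynamic program for Smith-Waterman
scores, and a duplicate survival-function fit for the PSM e-value.  They
share no code with the package paths they check.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from typing import List, Sequence, Tuple

import numpy as np

from venomscan.msa import BLOSUM62, GAP, Msa
from venomscan.profiles import AA_INDEX, ProfileHMM


def enumerate_viterbi(profile: ProfileHMM, peptide: str) -> float:
    """Best local path score by exhaustive enumeration (small inputs only).

    A path enters at any match state (free), moves through match / insert /
    delete states at transition cost ``log2(t / max(row))`` (odds against
    the most probable continuation from the source state), emits residues
    in bits against the background, and exits from any match state (free).
    The empty path scores 0.
    """
    n, M = len(peptide), profile.n_match
    if n == 0 or M == 0:
        return 0.0
    lt = np.log2(profile.transitions) - \
        np.log2(profile.transitions.max(axis=2, keepdims=True))
    em = np.log2(profile.match_emissions / profile.background)
    ei = np.log2(profile.insert_emissions / profile.background)
    xs = [AA_INDEX[a] for a in peptide]
    best = 0.0
    S = {"M": 0, "I": 1, "D": 2}

    def dfs(state: str, j: int, i: int, score: float) -> None:
        nonlocal best
        if state == "M":
            best = max(best, score)
        si = S[state]
        if i < n:
            if j < M:
                dfs("M", j + 1, i + 1, score + lt[j, si, 0] + em[j, xs[i]])
            dfs("I", j, i + 1, score + lt[j, si, 1] + ei[xs[i]])
        if j < M:
            dfs("D", j + 1, i, score + lt[j, si, 2])

    for i0 in range(n):
        for j0 in range(1, M + 1):
            dfs("M", j0, i0 + 1, em[j0 - 1, xs[i0]])
    return best


def local_gotoh(seq_a: str, seq_b: str, gap_open: float = -11.0,
                gap_extend: float = -1.0) -> float:
    """Smith-Waterman score under BLOSUM62 with affine gaps (plain DP)."""
    n, m = len(seq_a), len(seq_b)
    neg = float("-inf")
    open_c, ext_c = -abs(gap_open), -abs(gap_extend)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(H[i - 1][j] + open_c, X[i - 1][j] + ext_c,
                          Y[i - 1][j] + open_c)
            Y[i][j] = max(H[i][j - 1] + open_c, Y[i][j - 1] + ext_c,
                          X[i][j - 1] + open_c)
            s = float(BLOSUM62[seq_a[i - 1]][seq_b[j - 1]])
            H[i][j] = max(0.0,
                          s + max(H[i - 1][j - 1], X[i - 1][j - 1],
                                  Y[i - 1][j - 1]))
            best = max(best, H[i][j])
    return best


def refit_evalue(candidate_scores: Sequence[float], observed: float) -> float:
    """Duplicate survival-function fit, written independently.

    Same definition as the package: drop the single best score when three or
    more distinct values exist, fit log10(survival) against score over the
    upper half of the remaining distinct values with least squares, and
    evaluate at the observed score.  Degenerate fits give 1.0.
    """
    finite = sorted(s for s in candidate_scores if math.isfinite(s))
    if not finite or math.isinf(observed):
        return 1.0
    distinct = sorted(set(finite))
    if len(distinct) < 2:
        return 1.0
    if len(distinct) >= 3:
        distinct = distinct[:-1]
    upper = distinct[len(distinct) // 2:]
    if len(upper) < 2:
        upper = distinct[-2:]
    pts = []
    for x in upper:
        surv = len(finite) - bisect_left(finite, x)
        if surv > 0:
            pts.append((x, math.log10(surv)))
    if len(pts) < 2:
        return 1.0
    xbar = sum(p[0] for p in pts) / len(pts)
    ybar = sum(p[1] for p in pts) / len(pts)
    sxx = sum((p[0] - xbar) ** 2 for p in pts)
    if sxx == 0:
        return 1.0
    slope = sum((p[0] - xbar) * (p[1] - ybar) for p in pts) / sxx
    if slope >= 0:
        return 1.0
    intercept = ybar - slope * xbar
    return 10.0 ** (intercept + slope * observed)


def random_msa(rng: np.random.Generator, max_rows: int = 4,
               max_width: int = 8, alphabet: str = "ACDEGK") -> Msa:
    """A random (often cysteine-heterogeneous) alignment for split testing."""
    n_rows = int(rng.integers(1, max_rows + 1))
    width = int(rng.integers(2, max_width + 1))
    rows = []
    for r in range(n_rows):
        chars = []
        for _ in range(width):
            if rng.random() < 0.15:
                chars.append(GAP)
            elif rng.random() < 0.3:
                chars.append("C")
            else:
                chars.append(str(rng.choice(list(alphabet.replace("C", "")))))
        if all(c == GAP for c in chars):
            chars[0] = "A"
        rows.append((f"r{r}", "".join(chars)))
    return Msa(rows)


def random_profile(rng: np.random.Generator, max_match: int = 4) -> ProfileHMM:
    """A small random profile built through the package's own trainer from a
    gap-free random alignment (so only emission/transition values vary)."""
    from venomscan.profiles import build_profile

    width = int(rng.integers(1, max_match + 1))
    n_rows = int(rng.integers(1, 4))
    alphabet = list("ACDEG")
    rows = []
    for r in range(n_rows):
        rows.append((f"r{r}", "".join(str(rng.choice(alphabet))
                                      for _ in range(width))))
    # Homogenise cysteines: replace C by A to avoid accidental heterogeneity.
    rows = [(rid, row.replace("C", "A")) for rid, row in rows]
    return build_profile(Msa(rows))
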