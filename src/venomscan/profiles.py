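"""Toxin-family profile library construction.

The bespoke procedure at the heart of the transcriptome side of the
pipeline: reference toxins are clustered by single-linkage on local-alignment
identity, each cluster is progressively aligned, alignments are recursively
split until every part groups peptides with the same number of cysteines at
the same alignment columns, and one profile hidden Markov model is trained
per homogeneous alignment.

The profile architecture is the standard match/insert/delete layout (without
explicit flanking loops).  Emissions and transitions are maximum-likelihood
counts with Laplace smoothing, so every probability is strictly positive and
every state's distribution sums to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .msa import GAP, Msa, align_cluster, local_identity
from .scaffold import CysteineScaffold, scaffold_of
from .seqio import FastaRecord

__all__ = [
    "ProfileHMM",
    "LibraryProfile",
    "cluster_sequences",
    "is_homogeneous",
    "split_msa",
    "build_profile",
    "build_library",
    "save_library",
    "load_library",
    "AMINO_ACIDS",
    "AA_INDEX",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# State order used throughout: match, insert, delete.
_M, _I, _D = 0, 1, 2


@dataclass
class ProfileHMM:
    """Profile hidden Markov model over the 20 standard residues.

    ``match_emissions``  -- (M, 20) rows, one per match state.
    ``insert_emissions`` -- single shared 20-vector.
    ``transitions``      -- (M+1, 3, 3): ``transitions[j, s, t]`` is the
    probability of moving from state ``s`` in {M, I, D} at position *j* to
    state ``t``; "to match" at position j means M_{j+1} (position 0 acts as
    begin, position M's outgoing match is the end state).
    ``background``       -- null-model residue distribution.
    """

    n_match: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, float)
        self.insert_emissions = np.asarray(self.insert_emissions, float)
        self.transitions = np.asarray(self.transitions, float)
        self.background = np.asarray(self.background, float)
        if self.match_emissions.shape != (self.n_match, 20):
            raise ValueError("match_emissions must be (n_match, 20)")
        if self.transitions.shape != (self.n_match + 1, 3, 3):
            raise ValueError("transitions must be (n_match + 1, 3, 3)")
        for name, arr, axis in (
            ("match_emissions", self.match_emissions, 1),
            ("insert_emissions", self.insert_emissions[None, :], 1),
            ("background", self.background[None, :], 1),
        ):
            sums = arr.sum(axis=axis)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        tsums = self.transitions.sum(axis=2)
        if not np.allclose(tsums, 1.0, atol=1e-9) or np.any(self.transitions <= 0):
            raise ValueError("transition rows must be positive and sum to 1")

    def to_dict(self) -> dict:
        return {
            "n_match": self.n_match,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": self.transitions.tolist(),
            "background": self.background.tolist(),
            "pseudocount": self.pseudocount,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        return cls(
            n_match=d["n_match"],
            match_emissions=np.array(d["match_emissions"]),
            insert_emissions=np.array(d["insert_emissions"]),
            transitions=np.array(d["transitions"]),
            background=np.array(d["background"]),
            pseudocount=d.get("pseudocount", 1.0),
        )


@dataclass
class LibraryProfile:
    """A library entry: the model plus its provenance and family labels."""

    profile_id: str
    hmm: ProfileHMM
    family_id: str
    ick: bool
    member_ids: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_sequences(refs: Sequence[FastaRecord], min_identity: float = 0.35,
                      min_overlap: float = 0.80) -> List[List[FastaRecord]]:
    """Single-linkage clusters over local-alignment similarity.

    Two sequences are joined when their best local alignment reaches
    ``min_identity`` (matches / alignment columns) and spans at least
    ``min_overlap`` of the shorter sequence.  The partition is invariant to
    input order up to cluster labelling: clusters are reported sorted by
    their lexicographically smallest member id.
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    n = len(refs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            _, identity, coverage = local_identity(refs[i].seq, refs[j].seq)
            if identity >= min_identity and coverage >= min_overlap:
                parent[find(i)] = find(j)

    groups: Dict[int, List[FastaRecord]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(refs[i])
    clusters = [sorted(g, key=lambda r: r.id) for g in groups.values()]
    clusters.sort(key=lambda g: g[0].id)
    return clusters


# ---------------------------------------------------------------------------
# Homogeneity and recursive splitting
# ---------------------------------------------------------------------------

def _cys_columns(row: str) -> frozenset:
    return frozenset(i for i, ch in enumerate(row) if ch == "C")

def is_homogeneous(msa: Msa) -> bool:
    """True iff every row has cysteines in exactly the same alignment columns."""
    if not msa.rows:
        return True
    first = _cys_columns(msa.rows[0][1])
    return all(_cys_columns(row) == first for _, row in msa.rows[1:])


def split_msa(msa: Msa) -> List[Msa]:
    """Recursively split an alignment until every part is cysteine-homogeneous.

    Rows are grouped by their ungapped scaffold signature and each group is
    realigned and re-tested.  A group that shares a signature yet still
    fails column homogeneity (the aligner placed a cysteine against a
    non-cysteine) is bisected deterministically, which guarantees
    termination; singletons are homogeneous by construction.
    """
    if is_homogeneous(msa):
        return [msa]
    seqs = msa.ungapped()
    groups: Dict[Tuple[int, Tuple[int, ...]], List[Tuple[str, str]]] = {}
    for rid, seq in seqs:
        sc = scaffold_of(seq)
        groups.setdefault((sc.n_cys, sc.gaps), []).append((rid, seq))

    parts: List[List[Tuple[str, str]]]
    if len(groups) > 1:
        parts = [groups[key] for key in sorted(groups)]
    else:
        ordered = sorted(seqs, key=lambda t: t[0])
        parts = [ordered[: len(ordered) // 2], ordered[len(ordered) // 2:]]

    out: List[Msa] = []
    for part in parts:
        if not part:
            continue
        out.extend(split_msa(align_cluster(part)))
    return out


# ---------------------------------------------------------------------------
# Profile training
# ---------------------------------------------------------------------------

def build_profile(msa: Msa, pseudocount: float = 1.0,
                  match_threshold: float = 0.5) -> ProfileHMM:
    """Train a profile HMM from a cysteine-homogeneous alignment.

    Columns whose gap fraction is below ``match_threshold`` become match
    states.  Emissions are Laplace-smoothed counts,
    ``(count + a) / (residues_in_column + 20 a)``; transitions are smoothed
    the same way from the observed per-row state paths.
    """
    if not is_homogeneous(msa):
        raise ValueError("build_profile requires a cysteine-homogeneous MSA")
    if not msa.rows:
        raise ValueError("cannot build a profile from an empty MSA")
    a = float(pseudocount)
    n_rows = len(msa.rows)
    width = msa.width
    gap_frac = [
        sum(1 for _, row in msa.rows if row[j] == GAP) / n_rows
        for j in range(width)
    ]
    match_cols = [j for j in range(width) if gap_frac[j] < match_threshold]
    M = len(match_cols)
    col_rank = {j: k for k, j in enumerate(match_cols)}

    emit_counts = np.zeros((M, 20))
    insert_counts = np.zeros(20)
    trans_counts = np.zeros((M + 1, 3, 3))

    for _, row in msa.rows:
        state, pos = _M, 0  # begin = match at position 0
        for j in range(width):
            ch = row[j]
            if j in col_rank:
                k = col_rank[j]
                if ch == GAP:
                    trans_counts[pos, state, _D] += 1
                    state, pos = _D, k + 1
                else:
                    trans_counts[pos, state, _M] += 1
                    state, pos = _M, k + 1
                    if ch in AA_INDEX:
                        emit_counts[k, AA_INDEX[ch]] += 1
            else:
                if ch != GAP:
                    trans_counts[pos, state, _I] += 1
                    state = _I
                    if ch in AA_INDEX:
                        insert_counts[AA_INDEX[ch]] += 1
        trans_counts[pos, state, _M] += 1  # exit to end

    col_res = emit_counts.sum(axis=1, keepdims=True)
    match_emissions = (emit_counts + a) / (col_res + 20 * a)
    insert_emissions = (insert_counts + a) / (insert_counts.sum() + 20 * a)
    transitions = (trans_counts + a) / (
        trans_counts.sum(axis=2, keepdims=True) + 3 * a
    )
    background = np.full(20, 1.0 / 20)
    return ProfileHMM(
        n_match=M,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        background=background,
        pseudocount=a,
    )


def build_library(refs: Sequence[FastaRecord], min_identity: float = 0.35,
                  min_overlap: float = 0.80, min_members: int = 2,
                  pseudocount: float = 1.0) -> List[LibraryProfile]:
    """Cluster, align, split and train: one profile per homogeneous alignment.

    Each profile inherits the majority family label and ICK flag of its
    member sequences (ties broken toward the lexicographically smallest
    family).  Parts with fewer than ``min_members`` rows are skipped.
    """
    if not refs:
        return []
    label = {r.id: (r.family or "unknown") for r in refs}
    ick_label = {r.id: bool(r.ick) for r in refs}
    library: List[LibraryProfile] = []
    k = 0
    for cluster in cluster_sequences(refs, min_identity, min_overlap):
        msa = align_cluster([(r.id, r.seq) for r in cluster])
        for part in split_msa(msa):
            if len(part.rows) < min_members:
                continue
            members = [rid for rid, _ in part.rows]
            counts: Dict[str, int] = {}
            for m in members:
                counts[label[m]] = counts.get(label[m], 0) + 1
            top = max(counts.values())
            best_fam = min(f for f, c in counts.items() if c == top)
            ick_votes = sum(ick_label[m] for m in members)
            k += 1
            library.append(LibraryProfile(
                profile_id=f"prof{k:03d}",
                hmm=build_profile(part, pseudocount=pseudocount),
                family_id=best_fam,
                ick=ick_votes * 2 >= len(members),
                member_ids=members,
            ))
    return library


def save_library(library: Sequence[LibraryProfile], path) -> None:
    payload = [
        {
            "profile_id": p.profile_id,
            "family_id": p.family_id,
            "ick": p.ick,
            "member_ids": p.member_ids,
            "hmm": p.hmm.to_dict(),
        }
        for p in library
    ]
    Path(path).write_text(json.dumps(payload))


def load_library(path) -> List[LibraryProfile]:
    payload = json.loads(Path(path).read_text())
    return [
        LibraryProfile(
            profile_id=d["profile_id"],
            hmm=ProfileHMM.from_dict(d["hmm"]),
            family_id=d["family_id"],
            ick=d["ick"],
            member_ids=d.get("member_ids", []),
        )
        for d in payload
    ]
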