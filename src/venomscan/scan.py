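"""Putative-toxin retrieval from contigs.

Contigs are translated in all six frames into stop-to-stop open reading
frames, each ORF is scanned against every profile in the family library
with a local Viterbi alignment (log-odds in bits against a uniform null
model), and hits are filtered by read support, profile coverage and
residue cleanliness.  Frameshifted or misassembled contigs fail the
coverage criterion and are removed rather than repaired.

Mature-peptide boundaries are predicted from precursor processing logic:
the mature domain starts after the last basic residue (R/K) preceding the
first cysteine of the profile-matched region and runs to the C-terminus of
its ORF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .prep import Contig, revcomp
from .profiles import AA_INDEX, LibraryProfile, ProfileHMM

__all__ = [
    "Orf",
    "ProfileHit",
    "PutativeToxin",
    "ViterbiResult",
    "six_frame_orfs",
    "viterbi",
    "scan_library",
    "filter_putative",
    "extract_mature",
]

_M, _I, _D = 0, 1, 2


@dataclass(frozen=True)
class Orf:
    """A stop-to-stop open reading frame, with forward-strand coordinates."""

    contig_id: str
    frame: int  # +1,+2,+3 forward; -1,-2,-3 reverse
    start: int  # 0-based, half-open, on the forward strand
    end: int
    peptide: str

    @property
    def id(self) -> str:
        return f"{self.contig_id}|{self.frame:+d}|{self.start}-{self.end}"


@dataclass
class ViterbiResult:
    log_odds: float
    peptide_span: Optional[Tuple[int, int]]  # half-open residue coords
    match_span: Optional[Tuple[int, int]]    # 1-based match-state indices
    match_coverage: float


@dataclass
class ProfileHit:
    profile_id: str
    family_id: str
    ick: bool
    orf: Orf
    log_odds: float
    peptide_span: Tuple[int, int]
    match_coverage: float
    contig_support: int = 0
    is_best: bool = False
    profile_n_cys: int = 0  # cysteines in the profile's match-state consensus


@dataclass
class PutativeToxin:
    """A filtered transcriptome-derived toxin candidate."""

    contig_id: str
    orf: Orf
    mature: str
    profile_id: str
    family_id: str
    ick: bool
    score: float
    coverage: float
    support: int
    rpkm: float = 0.0


def six_frame_orfs(contig: Contig, min_orf_len: int = 10) -> List[Orf]:
    """All maximal stop-to-stop peptides of length >= ``min_orf_len`` in six frames.

    Coordinates map back to the forward strand; output order is by frame
    (+1, +2, +3, -1, -2, -3) then start coordinate.
    """
    out: List[Orf] = []
    L = len(contig.seq)
    for strand, seq in ((1, contig.seq), (-1, revcomp(contig.seq))):
        for off in range(3):
            n_codons = (L - off) // 3
            if n_codons <= 0:
                continue
            sub = seq[off:off + 3 * n_codons]
            pep = str(Seq(sub).translate())
            pos = 0
            for stretch in pep.split("*"):
                if len(stretch) >= min_orf_len:
                    s_aa, e_aa = pos, pos + len(stretch)
                    nt0, nt1 = off + 3 * s_aa, off + 3 * e_aa
                    if strand == 1:
                        start, end = nt0, nt1
                    else:
                        start, end = L - nt1, L - nt0
                    out.append(Orf(contig.id, strand * (off + 1), start, end,
                                   stretch))
                pos += len(stretch) + 1
    frame_order = {f: i for i, f in enumerate((1, 2, 3, -1, -2, -3))}
    out.sort(key=lambda o: (frame_order[o.frame], o.start))
    return out


def viterbi(profile: ProfileHMM, peptide: str) -> ViterbiResult:
    """Best local log-odds alignment of a peptide through the profile.

    Entry and exit are free at any match state; emissions are scored in bits
    against the background.  Transitions are scored against the most
    probable continuation from their source state, ``log2(t / max(row))``:
    the canonical match-match path is transition-free and every deviation
    (gap open, insert, delete) costs, so extension of a well-matching
    peptide is driven by its emission log-odds alone.  The empty alignment
    scores 0.
    """
    n, M = len(peptide), profile.n_match
    if n == 0 or M == 0:
        return ViterbiResult(0.0, None, None, 0.0)
    NEG = -1e30
    log_t = np.log2(
        profile.transitions / profile.transitions.max(axis=2, keepdims=True)
    )                                                          # (M+1,3,3)
    lo_match = np.log2(profile.match_emissions / profile.background)  # (M,20)
    lo_ins = np.log2(profile.insert_emissions / profile.background)   # (20,)
    xs = [AA_INDEX.get(aa, -1) for aa in peptide]

    VM = np.full((n, M + 1), NEG)
    VI = np.full((n, M + 1), NEG)
    VD = np.full((n, M + 1), NEG)
    bpM = np.zeros((n, M + 1), dtype=np.int8)  # 0 entry, 1 M, 2 I, 3 D
    bpI = np.zeros((n, M + 1), dtype=np.int8)
    bpD = np.zeros((n, M + 1), dtype=np.int8)

    tMM = log_t[:M, _M, _M]
    tIM = log_t[:M, _I, _M]
    tDM = log_t[:M, _D, _M]
    tMD = log_t[:M, _M, _D]
    tID = log_t[:M, _I, _D]
    tDD = log_t[:M, _D, _D]
    tMI = log_t[:, _M, _I]
    tII = log_t[:, _I, _I]
    tDI = log_t[:, _D, _I]

    for i in range(n):
        xi = xs[i]
        # Unknown residue: emits nowhere (treated as strongly penalised).
        ecol = lo_match[:, xi] if xi >= 0 else np.full(M, NEG / 2)
        eins = lo_ins[xi] if xi >= 0 else NEG / 2
        if i == 0:
            VM[0, 1:] = ecol  # entry only
            bpM[0, 1:] = 0
        else:
            cands = np.stack([
                np.zeros(M),                       # entry
                VM[i - 1, 0:M] + tMM,
                VI[i - 1, 0:M] + tIM,
                VD[i - 1, 0:M] + tDM,
            ])
            best = np.argmax(cands, axis=0)
            VM[i, 1:] = ecol + cands[best, np.arange(M)]
            bpM[i, 1:] = best
            icands = np.stack([
                VM[i - 1, :] + tMI,
                VI[i - 1, :] + tII,
                VD[i - 1, :] + tDI,
            ])
            ibest = np.argmax(icands, axis=0)
            VI[i, :] = eins + icands[ibest, np.arange(M + 1)]
            bpI[i, :] = ibest + 1
        # Delete chain within row (consumes no residue).
        for j in range(2, M + 1):
            a = VM[i, j - 1] + tMD[j - 1]
            b = VI[i, j - 1] + tID[j - 1]
            c = VD[i, j - 1] + tDD[j - 1]
            if a >= b and a >= c:
                VD[i, j], bpD[i, j] = a, 1
            elif b >= c:
                VD[i, j], bpD[i, j] = b, 2
            else:
                VD[i, j], bpD[i, j] = c, 3

    flat = np.argmax(VM[:, 1:])
    i_end, j_end = divmod(int(flat), M)
    j_end += 1
    best_score = float(VM[i_end, j_end])
    if best_score <= 0.0:
        return ViterbiResult(0.0, None, None, 0.0)

    # Traceback to the entry cell.
    i, j, state = i_end, j_end, "M"
    i0, j0 = i, j
    while True:
        if state == "M":
            code = bpM[i, j]
            if code == 0:
                i0, j0 = i, j
                break
            state = {1: "M", 2: "I", 3: "D"}[int(code)]
            if state == "D":
                i, j = i - 1, j - 1
            else:
                i, j = i - 1, j - 1
        elif state == "I":
            code = bpI[i, j]
            state = {1: "M", 2: "I", 3: "D"}[int(code)]
            i = i - 1
        else:  # D
            code = bpD[i, j]
            state = {1: "M", 2: "I", 3: "D"}[int(code)]
            j = j - 1
    coverage = (j_end - j0 + 1) / M
    return ViterbiResult(best_score, (i0, i_end + 1), (j0, j_end), coverage)


def scan_library(library: Sequence[LibraryProfile], orfs: Sequence[Orf],
                 score_threshold: float = 10.0) -> List[ProfileHit]:
    """Score every (profile, ORF) pair; emit hits at or above the threshold.

    The best profile per ORF is flagged; ties go to the lexicographically
    smallest profile id.
    """
    if not library:
        raise ValueError("profile library is empty")
    hits: List[ProfileHit] = []
    for orf in orfs:
        orf_hits: List[ProfileHit] = []
        for prof in sorted(library, key=lambda p: p.profile_id):
            res = viterbi(prof.hmm, orf.peptide)
            if res.log_odds >= score_threshold and res.peptide_span is not None:
                orf_hits.append(ProfileHit(
                    profile_id=prof.profile_id,
                    family_id=prof.family_id,
                    ick=prof.ick,
                    orf=orf,
                    log_odds=res.log_odds,
                    peptide_span=res.peptide_span,
                    match_coverage=res.match_coverage,
                    profile_n_cys=consensus_n_cys(prof.hmm),
                ))
        if orf_hits:
            best = min(orf_hits, key=lambda h: (-h.log_odds, h.profile_id))
            best.is_best = True
        hits.extend(orf_hits)
    return hits


def consensus_n_cys(profile: ProfileHMM) -> int:
    """Cysteine count of the profile's match-state consensus sequence."""
    import numpy as _np
    from .profiles import AMINO_ACIDS as _AA

    idx = _np.argmax(profile.match_emissions, axis=1)
    return sum(1 for k in idx if _AA[k] == "C")


def extract_mature(orf_peptide: str, peptide_span: Tuple[int, int]) -> str:
    """Predict the mature peptide for a profile-matched ORF region.

    Precursor processing cleaves after the last basic residue preceding the
    mature domain, and the mature domain ends at the precursor C-terminus:
    the mature peptide starts after the last R/K before the first cysteine
    of the matched region and runs to the end of the ORF.
    """
    start = peptide_span[0]
    first_cys = orf_peptide.find("C", start)
    bound = first_cys if first_cys >= 0 else start
    cleave = -1
    for p in range(bound - 1, -1, -1):
        if orf_peptide[p] in "RK":
            cleave = p
            break
    return orf_peptide[cleave + 1:] if cleave >= 0 else orf_peptide[start:]


def filter_putative(hits: Sequence[ProfileHit], support: Dict[str, int],
                    min_reads: int = 10, min_coverage: float = 0.9,
                    rpkm_by_contig: Optional[Dict[str, float]] = None,
                    min_cys: int = 2,
                    ) -> Tuple[List[PutativeToxin], List[Tuple[ProfileHit, str]]]:
    """Apply the quality filters to best-per-ORF hits.

    Keeps hits whose contig has read support >= ``min_reads``, whose profile
    coverage is >= ``min_coverage`` (partial ORFs and frameshifts fail
    here), whose aligned span is free of ambiguous residues, and whose
    predicted mature peptide is cysteine-pattern congruent with the profile
    that found it: at least ``min_cys`` cysteines overall and the same
    cysteine count as the profile's match-state consensus (family profiles
    are scaffold-homogeneous by construction, so a scaffold-discordant hit
    -- typically an antisense-frame shadow ORF -- is spurious).  Returns
    (kept records, removed hits with reasons).
    """
    kept: List[PutativeToxin] = []
    removed: List[Tuple[ProfileHit, str]] = []
    for hit in hits:
        if not hit.is_best:
            continue
        supp = support.get(hit.orf.contig_id, 0)
        span = hit.orf.peptide[hit.peptide_span[0]:hit.peptide_span[1]]
        if supp < min_reads:
            removed.append((hit, "low_support"))
        elif hit.match_coverage < min_coverage:
            removed.append((hit, "partial_orf"))
        elif "X" in span or "*" in span:
            removed.append((hit, "ambiguous"))
        elif extract_mature(hit.orf.peptide, hit.peptide_span).count("C") < \
                min_cys:
            removed.append((hit, "low_cys"))
        elif hit.profile_n_cys and \
                extract_mature(hit.orf.peptide, hit.peptide_span).count("C") \
                != hit.profile_n_cys:
            removed.append((hit, "scaffold_mismatch"))
        else:
            hit.contig_support = supp
            kept.append(PutativeToxin(
                contig_id=hit.orf.contig_id,
                orf=hit.orf,
                mature=extract_mature(hit.orf.peptide, hit.peptide_span),
                profile_id=hit.profile_id,
                family_id=hit.family_id,
                ick=hit.ick,
                score=hit.log_odds,
                coverage=hit.match_coverage,
                support=supp,
                rpkm=(rpkm_by_contig or {}).get(hit.orf.contig_id, 0.0),
            ))
    return kept, removed
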