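"""Peptide-spectrum matching for intact reduced venom peptides.

Whole (undigested) mature peptides are matched against translated-contig
peptides: candidates are ORF peptides and their prefixes/suffixes whose
monoisotopic mass fits the precursor window.  Scoring is an X!Tandem-style
hyperscore, ``log10(sum of matched intensities * n_b! * n_y!)`` over
singly-charged monoisotopic b/y ions (cysteine at native mass -- the venom
is reduced but not alkylated), and significance is an expectation value
from a linear survival-function fit over the candidate score histogram.
"""

from __future__ import annotations

import hashlib
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "PROTON", "WATER",
    "Spectrum", "Psm", "PsmConfig",
    "peptide_mass", "theoretical_ions", "hyperscore", "evalue_fit",
    "search", "validate",
]

PROTON = 1.00727646688
WATER = 18.0105646863

# Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASS: Dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

NO_MATCH = float("-inf")


@dataclass
class Spectrum:
    """An MS/MS spectrum with peaks sorted by m/z."""

    id: str
    precursor_mz: float
    charge: int
    peaks: List[Tuple[float, float]]

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        self.peaks = sorted(self.peaks)
        if any(not math.isfinite(i) or i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be finite and non-negative")

    @property
    def neutral_mass(self) -> float:
        return self.precursor_mz * self.charge - self.charge * PROTON

    @property
    def total_intensity(self) -> float:
        return sum(i for _, i in self.peaks)

    @classmethod
    def from_mgf_dict(cls, d: dict) -> "Spectrum":
        params = d.get("params", {})
        charge = params.get("charge", [2])
        charge = int(charge[0]) if hasattr(charge, "__getitem__") else int(charge)
        return cls(
            id=str(params.get("title", "spectrum")),
            precursor_mz=float(params["pepmass"][0]),
            charge=abs(charge),
            peaks=list(zip(map(float, d["m/z array"]),
                           map(float, d["intensity array"]))),
        )


@dataclass
class Psm:
    """A peptide-spectrum match."""

    spectrum_id: str
    peptide: str
    n_b_matched: int
    n_y_matched: int
    hyperscore: float
    evalue: float
    matched_intensity_fraction: float = 0.0
    source_orf_id: Optional[str] = None


@dataclass(frozen=True)
class PsmConfig:
    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.02
    evalue_cutoff: float = 1.0
    min_cys: int = 2
    min_snr_fraction: float = 0.2
    min_candidates: int = 10

    def __post_init__(self) -> None:
        for name in ("precursor_tol_ppm", "fragment_tol_da", "evalue_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def peptide_mass(peptide: str) -> float:
    """Neutral monoisotopic mass of an unmodified peptide."""
    try:
        return sum(RESIDUE_MASS[aa] for aa in peptide) + WATER
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {peptide!r}") from None


def theoretical_ions(peptide: str) -> Tuple[List[float], List[float]]:
    """Singly-charged monoisotopic b1..b(n-1) and y1..y(n-1) fragment m/z."""
    if len(peptide) < 1:
        raise ValueError("peptide must be non-empty")
    masses = [RESIDUE_MASS.get(aa) for aa in peptide]
    if None in masses:
        bad = peptide[masses.index(None)]
        raise ValueError(f"unknown residue {bad!r} in {peptide!r}")
    b = []
    acc = 0.0
    for m in masses[:-1]:
        acc += m
        b.append(acc + PROTON)
    y = []
    acc = WATER
    for m in reversed(masses[1:]):
        acc += m
        y.append(acc + PROTON)
    return b, y


def _match_peaks(spectrum: Spectrum, peptide: str, fragment_tol: float
                 ) -> Tuple[float, int, int]:
    """Greedy nearest-peak assignment; each peak matches at most one ion."""
    b_mz, y_mz = theoretical_ions(peptide)
    mzs = [p[0] for p in spectrum.peaks]
    matched = [False] * len(spectrum.peaks)
    intensity = 0.0
    n_b = n_y = 0
    for series, ions in (("b", b_mz), ("y", y_mz)):
        for ion in ions:
            lo = bisect_left(mzs, ion - fragment_tol)
            hi = bisect_right(mzs, ion + fragment_tol)
            best_k = -1
            best_d = None
            for k in range(lo, hi):
                if matched[k]:
                    continue
                d = abs(mzs[k] - ion)
                if best_d is None or d < best_d:
                    best_d, best_k = d, k
            if best_k >= 0:
                matched[best_k] = True
                intensity += spectrum.peaks[best_k][1]
                if series == "b":
                    n_b += 1
                else:
                    n_y += 1
    return intensity, n_b, n_y


def hyperscore(spectrum: Spectrum, peptide: str, fragment_tol: float = 0.02
               ) -> Tuple[float, int, int]:
    """X!Tandem-style hyperscore of a peptide against a spectrum.

    Each observed peak matches at most one theoretical ion (the nearest
    within +/- ``fragment_tol``); the score is
    ``log10(matched_intensity_sum * n_b! * n_y!)``, or ``-inf`` when
    nothing matches.
    """
    intensity, n_b, n_y = _match_peaks(spectrum, peptide, fragment_tol)
    if n_b + n_y == 0 or intensity <= 0:
        return NO_MATCH, n_b, n_y
    log_fact = (math.lgamma(n_b + 1) + math.lgamma(n_y + 1)) / math.log(10)
    return math.log10(intensity) + log_fact, n_b, n_y


def evalue_fit(candidate_scores: Sequence[float], observed_score: float) -> float:
    """Expectation value from a survival-function fit of candidate hyperscores.

    log10(number of candidates scoring >= x) is fit linearly against x over
    the upper half of the finite-score histogram; the e-value is
    ``10 ** (intercept + slope * observed_score)``, clamped to a
    non-increasing function of score.  Degenerate fits (all scores equal,
    or a non-negative slope) return 1.0 by convention.
    """
    finite = sorted(s for s in candidate_scores if math.isfinite(s))
    if not finite or math.isinf(observed_score):
        return 1.0
    xs = sorted(set(finite))
    if len(xs) < 2:
        return 1.0
    # Fit the candidate bulk: the single best score is excluded so a genuine
    # hit is judged against the distribution of the remaining candidates.
    if len(xs) >= 3:
        xs = xs[:-1]
    upper = xs[len(xs) // 2:]
    if len(upper) < 2:
        upper = xs[-2:]
    n = len(finite)
    pts = []
    for x in upper:
        survival = n - bisect_left(finite, x)
        if survival > 0:
            pts.append((x, math.log10(survival)))
    if len(pts) < 2:
        return 1.0
    px = np.array([p[0] for p in pts])
    py = np.array([p[1] for p in pts])
    slope, intercept = np.polyfit(px, py, 1)
    if not np.isfinite(slope) or slope >= 0:
        return 1.0
    return float(10.0 ** (intercept + slope * observed_score))


def _decoy_scores(spectrum: Spectrum, peptides: Sequence[str], need: int,
                  fragment_tol: float) -> List[float]:
    """Scores of deterministic residue permutations, to pad thin candidate sets."""
    seed = int.from_bytes(
        hashlib.sha256(spectrum.id.encode()).digest()[:4], "big") & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    scores: List[float] = []
    k = 0
    while len(scores) < need and k < 4 * need:
        base = peptides[k % len(peptides)]
        perm = "".join(rng.permutation(list(base)))
        s, _, _ = hyperscore(spectrum, perm, fragment_tol)
        if math.isfinite(s):
            scores.append(s)
        k += 1
    return scores


def search(spectra: Sequence[Spectrum], orf_peptides: Sequence[Tuple[str, str]],
           config: Optional[PsmConfig] = None) -> List[Psm]:
    """Match each spectrum against ORF-derived candidates; keep the best PSM.

    Candidates are whole ORF peptides plus their prefixes and suffixes whose
    neutral mass lies within ``precursor_tol_ppm`` of the precursor (no
    enzymatic digestion is modelled: the venom is analysed intact).  A
    spectrum yields a PSM only when its best candidate has
    ``evalue < evalue_cutoff``.
    """
    config = config or PsmConfig()
    # Precompute prefix masses per ORF peptide.
    entries = []
    for oid, pep in orf_peptides:
        if not pep or any(aa not in RESIDUE_MASS for aa in pep):
            continue
        prefix = [0.0]
        for aa in pep:
            prefix.append(prefix[-1] + RESIDUE_MASS[aa])
        entries.append((oid, pep, prefix))

    psms: List[Psm] = []
    for spectrum in spectra:
        target = spectrum.neutral_mass
        tol = target * config.precursor_tol_ppm * 1e-6
        cands: List[Tuple[str, str]] = []
        seen = set()
        for oid, pep, prefix in entries:
            total = prefix[-1]
            n = len(pep)
            # prefixes pep[:k], suffixes pep[k:] (whole peptide included).
            for k in range(1, n + 1):
                if abs(prefix[k] + WATER - target) <= tol:
                    sub = pep[:k]
                    if (oid, sub) not in seen:
                        seen.add((oid, sub))
                        cands.append((oid, sub))
            for k in range(0, n):
                if abs(total - prefix[k] + WATER - target) <= tol:
                    sub = pep[k:]
                    if (oid, sub) not in seen:
                        seen.add((oid, sub))
                        cands.append((oid, sub))
        if not cands:
            continue
        scored = []
        for oid, pep in cands:
            s, n_b, n_y = hyperscore(spectrum, pep, config.fragment_tol_da)
            scored.append((s, n_b, n_y, pep, oid))
        all_scores = [s[0] for s in scored]
        finite = [s for s in all_scores if math.isfinite(s)]
        if len(finite) < config.min_candidates:
            pool = [pep for _, _, _, pep, _ in scored] or [p for _, p in orf_peptides]
            finite += _decoy_scores(spectrum, pool,
                                    config.min_candidates - len(finite),
                                    config.fragment_tol_da)
        best = max(scored, key=lambda t: (t[0], t[3]))
        if not math.isfinite(best[0]):
            continue
        ev = evalue_fit(finite, best[0])
        if ev >= config.evalue_cutoff:
            continue
        matched_int, _, _ = _match_peaks(spectrum, best[3], config.fragment_tol_da)
        total_int = spectrum.total_intensity
        psms.append(Psm(
            spectrum_id=spectrum.id,
            peptide=best[3],
            n_b_matched=best[1],
            n_y_matched=best[2],
            hyperscore=best[0],
            evalue=max(ev, 1e-300),
            matched_intensity_fraction=matched_int / total_int if total_int else 0.0,
            source_orf_id=best[4],
        ))
    return psms


def validate(psms: Sequence[Psm], min_cys: int = 2, min_snr_fraction: float = 0.2
             ) -> Tuple[List[Psm], List[Tuple[Psm, str]]]:
    """Post-search validation of PSMs.

    Retains peptides with at least ``min_cys`` cysteines, discards any whose
    matched span contains a stop symbol, and applies an automated
    signal-to-noise proxy: the matched-intensity fraction of the spectrum
    must reach ``min_snr_fraction``.
    """
    kept: List[Psm] = []
    removed: List[Tuple[Psm, str]] = []
    for psm in psms:
        if "*" in psm.peptide:
            removed.append((psm, "stop_codon"))
        elif psm.peptide.count("C") < min_cys:
            removed.append((psm, "low_cys"))
        elif psm.matched_intensity_fraction < min_snr_fraction:
            removed.append((psm, "low_snr"))
        else:
            kept.append(psm)
    return kept, removed
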