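"""Cysteine scaffolds: the classification currency of cysteine-rich venom peptides.

A scaffold is the count of cysteines in an ungapped peptide together with the
number of residues strictly between each consecutive pair.  It is a sequence-level
proxy for disulfide architecture: peptides sharing a scaffold are presumed to share
a fold.  The inhibitor cystine knot (ICK, "knottin") fold is recognised here by a
spacing envelope over the first six cysteines; its presumed connectivity is
C1-C4, C2-C5, C3-C6, with the third bridge threading the ring closed by the
first two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

__all__ = [
    "CysteineScaffold",
    "scaffold_of",
    "KNOTTIN_ENVELOPE",
    "matches_knottin_envelope",
    "ick_connectivity",
]


@dataclass(frozen=True)
class CysteineScaffold:
    """Cysteine count plus ordered inter-cysteine gap lengths.

    ``gaps`` has length ``n_cys - 1`` (empty for fewer than two cysteines);
    entry *i* is the number of residues strictly between cysteine *i+1* and
    cysteine *i+2*.
    """

    n_cys: int
    gaps: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_cys < 0:
            raise ValueError("n_cys must be non-negative")
        object.__setattr__(self, "gaps", tuple(int(g) for g in self.gaps))
        if any(g < 0 for g in self.gaps):
            raise ValueError("gap lengths must be non-negative")
        expected = max(self.n_cys - 1, 0)
        if len(self.gaps) != expected:
            raise ValueError(
                f"scaffold with {self.n_cys} cysteines needs {expected} gaps, "
                f"got {len(self.gaps)}"
            )

    @property
    def span(self) -> int:
        """Residues from the first to the last cysteine, inclusive."""
        if self.n_cys == 0:
            return 0
        return self.n_cys + sum(self.gaps)

    def __str__(self) -> str:  # e.g. "C6:6-6-0-4-8"
        return f"C{self.n_cys}:" + "-".join(str(g) for g in self.gaps)


def scaffold_of(seq: str) -> CysteineScaffold:
    """Extract the cysteine scaffold of an ungapped residue string."""
    positions = [i for i, aa in enumerate(seq) if aa == "C"]
    gaps = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    return CysteineScaffold(len(positions), gaps)


# Inter-cysteine spacing bounds (min, max residues) for the knottin fold,
# over gaps C1..C2 through C5..C6.
KNOTTIN_ENVELOPE: Tuple[Tuple[int, int], ...] = (
    (3, 10),
    (3, 12),
    (0, 7),
    (1, 12),
    (1, 15),
)


def matches_knottin_envelope(
    scaffold: CysteineScaffold,
    envelope: Sequence[Tuple[int, int]] = KNOTTIN_ENVELOPE,
) -> bool:
    """True when the first six cysteines fit the knottin spacing envelope.

    Scaffolds with fewer than six cysteines never match; extra cysteines
    beyond the sixth do not disqualify (many ICK toxins carry a fourth,
    non-knot disulfide).
    """
    if scaffold.n_cys < 6:
        return False
    first_gaps = scaffold.gaps[:5]
    return all(lo <= g <= hi for g, (lo, hi) in zip(first_gaps, envelope))


def ick_connectivity(scaffold: CysteineScaffold) -> Tuple[Tuple[int, int], ...]:
    """Presumed disulfide pairing of the first six cysteines: C1-C4, C2-C5, C3-C6."""
    if scaffold.n_cys < 6:
        raise ValueError("ICK connectivity requires at least six cysteines")
    return ((1, 4), (2, 5), (3, 6))
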