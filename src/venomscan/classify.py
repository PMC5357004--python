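"""Evidence unification, homology classification, ICK annotation and reporting.

Transcriptome- and proteome-derived mature peptides are merged into
non-redundant toxin records, classified by best local-alignment hit against
a labelled reference database (Smith-Waterman under BLOSUM62 with a
Karlin-Altschul-style expectation value), annotated for the inhibitor
cystine knot motif, given rational names in the style
``<descriptor><class>-<family>toxin-<species><paralog><isoform>``, and
tallied into per-species summary tables with cross-species totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from .msa import local_identity
from .scaffold import CysteineScaffold, matches_knottin_envelope, scaffold_of
from .seqio import FastaRecord

__all__ = [
    "ToxinRecord", "ClassificationResult", "SummaryTable", "NameRegistry",
    "local_align", "classify", "annotate_ick", "assign_name",
    "merge_evidence", "summarize", "round_half_up",
    "UNCHARACTERIZED", "COUNT_COLUMNS",
]

UNCHARACTERIZED = "uncharacterized"

# Gapped BLOSUM62 (open 11, extend 1) Karlin-Altschul constants.
KA_LAMBDA = 0.267
KA_K = 0.041

ALLOWED_DESCRIPTORS = {
    "U", "omega", "beta", "mu", "kappa", "delta", "alpha", "gamma", "tau",
    "pi", "theta", "epsilon", "lambda", "sigma",
}


@dataclass
class ToxinRecord:
    """Unified evidence record for one non-redundant mature peptide."""

    id: str
    species: str
    mature: str
    transcriptome: bool = False
    proteome: bool = False
    family: str = UNCHARACTERIZED
    ick: bool = False
    rpkm: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.transcriptome or self.proteome):
            raise ValueError(f"record {self.id}: at least one evidence flag required")

    @property
    def scaffold(self) -> CysteineScaffold:
        return scaffold_of(self.mature)


@dataclass(frozen=True)
class ClassificationResult:
    best_ref_id: str
    family: str
    bitscore: float
    evalue: float
    identity: float


def local_align(query: str, ref: str, gap_open: float = -11.0,
                gap_extend: float = -1.0, db_size: Optional[int] = None,
                ) -> Tuple[float, float, float]:
    """Best local alignment of two peptides: (raw score, identity, e-value).

    The expectation value follows the Karlin-Altschul form
    ``K * m * n * exp(-lambda * S)`` with gapped-BLOSUM62 constants, where
    *m* is the query length and *n* the (effective) database length --
    ``db_size`` if given, else the reference length.  A score of zero or
    less is reported as no hit (identity 0, e-value ``inf``).
    """
    if not query or not ref:
        raise ValueError("query and reference must be non-empty")
    score, identity, _ = local_identity(query, ref, gap_open, gap_extend)
    if score <= 0:
        return 0.0, 0.0, float("inf")
    n = db_size if db_size is not None else len(ref)
    evalue = KA_K * len(query) * n * math.exp(-KA_LAMBDA * score)
    return score, identity, max(evalue, 1e-300)


def classify(mature: str, refdb: Sequence[FastaRecord],
             evalue_cutoff: float = 1.0
             ) -> Union[ClassificationResult, str]:
    """Assign a family by best reference hit with ``evalue < evalue_cutoff``.

    Ties on e-value break by bitscore, then reference id.  An empty
    database or no hit below the cutoff yields ``"uncharacterized"``.
    """
    if not refdb:
        return UNCHARACTERIZED
    total_len = sum(len(r.seq) for r in refdb)
    best: Optional[ClassificationResult] = None
    for ref in refdb:
        score, identity, evalue = local_align(mature, ref.seq, db_size=total_len)
        if score <= 0:
            continue
        bitscore = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)
        cand = ClassificationResult(
            best_ref_id=ref.id,
            family=ref.family or UNCHARACTERIZED,
            bitscore=bitscore,
            evalue=evalue,
            identity=identity,
        )
        if best is None or (cand.evalue, -cand.bitscore, cand.best_ref_id) < \
                (best.evalue, -best.bitscore, best.best_ref_id):
            best = cand
    if best is None or best.evalue >= evalue_cutoff:
        return UNCHARACTERIZED
    return best


def annotate_ick(record: ToxinRecord,
                 family_ick_labels: Dict[str, bool]) -> bool:
    """ICK flag: propagate the family label, or match the knottin envelope.

    A record is flagged when its assigned family is ICK-labelled or when its
    own scaffold carries at least six cysteines spaced within the knottin
    envelope.  Fewer than six cysteines never flag (true connectivity is
    unobservable from sequence; the motif needs three disulfides).
    """
    sc = record.scaffold
    if sc.n_cys < 6:
        return False
    if family_ick_labels.get(record.family, False):
        return True
    return matches_knottin_envelope(sc)


class NameRegistry:
    """Issues rational toxin names, bumping the paralog number on collision."""

    def __init__(self) -> None:
        self._taken: Set[str] = set()

    def assign(self, activity_descriptor: str, class_number: int,
               family_stem: str, species_abbrev: str, paralog_number: int,
               isoform_letter: Optional[str] = None) -> str:
        if activity_descriptor not in ALLOWED_DESCRIPTORS:
            raise ValueError(f"unknown activity descriptor {activity_descriptor!r}")
        if not species_abbrev:
            raise ValueError("species abbreviation must be non-empty")
        paralog = paralog_number
        while True:
            name = (f"{activity_descriptor}{class_number}-{family_stem}-"
                    f"{species_abbrev}{paralog}{isoform_letter or ''}")
            if name not in self._taken:
                self._taken.add(name)
                return name
            paralog += 1


def assign_name(activity_descriptor: str, class_number: int, family_stem: str,
                species_abbrev: str, paralog_number: int,
                isoform_letter: Optional[str] = None,
                registry: Optional[NameRegistry] = None) -> str:
    """One-shot rational name, e.g. ``U1-sparatoxin-Hdb5``."""
    return (registry or NameRegistry()).assign(
        activity_descriptor, class_number, family_stem, species_abbrev,
        paralog_number, isoform_letter)


def merge_evidence(proteome_records: Sequence[ToxinRecord],
                   transcriptome_records: Sequence[ToxinRecord],
                   ) -> Tuple[List[ToxinRecord], int]:
    """Merge the two evidence streams into a non-redundant record set.

    Records with identical mature sequence (within a species) merge and
    carry both evidence flags; the count of shared sequences is returned.
    The merge is idempotent and commutative.
    """
    merged: Dict[Tuple[str, str], ToxinRecord] = {}
    for rec in list(proteome_records) + list(transcriptome_records):
        key = (rec.species, rec.mature)
        if key not in merged:
            merged[key] = ToxinRecord(
                id=rec.id, species=rec.species, mature=rec.mature,
                transcriptome=rec.transcriptome, proteome=rec.proteome,
                family=rec.family, ick=rec.ick, rpkm=rec.rpkm, name=rec.name,
            )
        else:
            cur = merged[key]
            cur.transcriptome = cur.transcriptome or rec.transcriptome
            cur.proteome = cur.proteome or rec.proteome
            if cur.rpkm is None:
                cur.rpkm = rec.rpkm
    records = list(merged.values())
    shared = sum(1 for r in records if r.transcriptome and r.proteome)
    return records, shared


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


COUNT_COLUMNS = [
    "validated_msms", "uncharacterized", "homologous",
    "hmm_putative", "hmm_in_venom", "total_sequences",
    "ick_count", "n_ick_families",
]


@dataclass
class SummaryTable:
    """Per-species toxin tallies with a cross-species total row.

    Count columns sum across species in the ``Total`` row; ``ick_percent``
    is recomputed from the total counts (a percentage does not add).
    """

    table: pd.DataFrame

    @classmethod
    def from_counts(cls, per_species: Dict[str, Dict[str, int]]) -> "SummaryTable":
        """Build from per-species counts, deriving totals and percentages.

        ``total_sequences`` is derived as
        ``validated_msms + hmm_putative - hmm_in_venom`` when absent, and
        ``ick_percent`` is always recomputed (rounded half-up).
        """
        rows = {}
        for sp, c in per_species.items():
            c = dict(c)
            c.setdefault(
                "total_sequences",
                c.get("validated_msms", 0) + c.get("hmm_putative", 0)
                - c.get("hmm_in_venom", 0),
            )
            for col in COUNT_COLUMNS:
                c.setdefault(col, 0)
            rows[sp] = {col: int(c[col]) for col in COUNT_COLUMNS}
        df = pd.DataFrame.from_dict(rows, orient="index")[COUNT_COLUMNS]
        totals = df.sum(axis=0)
        df.loc["Total"] = totals
        pct = []
        for sp in df.index:
            tot = df.loc[sp, "total_sequences"]
            pct.append(round_half_up(100.0 * df.loc[sp, "ick_count"] / tot)
                       if tot else 0)
        df["ick_percent"] = pct
        return cls(df)

    @property
    def totals(self) -> pd.Series:
        return self.table.loc["Total"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="species")

    def to_text(self) -> str:
        return self.table.to_string()


def summarize(records_per_species: Dict[str, Sequence[ToxinRecord]]
              ) -> SummaryTable:
    """Tally classified, ICK-annotated records into the summary table."""
    counts: Dict[str, Dict[str, int]] = {}
    for sp, records in records_per_species.items():
        proteome = [r for r in records if r.proteome]
        counts[sp] = {
            "validated_msms": len(proteome),
            "uncharacterized": sum(1 for r in proteome
                                   if r.family == UNCHARACTERIZED),
            "homologous": sum(1 for r in proteome
                              if r.family != UNCHARACTERIZED),
            "hmm_putative": sum(1 for r in records if r.transcriptome),
            "hmm_in_venom": sum(1 for r in records
                                if r.transcriptome and r.proteome),
            "total_sequences": len(records),
            "ick_count": sum(1 for r in records if r.ick),
            "n_ick_families": len({r.family for r in records if r.ick}),
        }
    return SummaryTable.from_counts(counts)
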