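"""End-to-end orchestration: reads and spectra in, classified toxin records out.

Per species: clean reads (rRNA, carry-over, duplicates), assemble, count
support and RPKM, scan supported contigs with the profile library, search
the MS/MS spectra against all translated contigs, merge the two evidence
streams, classify against the reference database, annotate the ICK motif
and assign rational names.  ``evaluate_study`` scores a run against the
generator's truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import msms, prep, scan
from .classify import (NameRegistry, SummaryTable, ToxinRecord,
                       UNCHARACTERIZED, annotate_ick, merge_evidence,
                       summarize)
from .classify import classify as classify_record
from .profiles import LibraryProfile, build_library
from .seqio import FastaRecord
from .simulate import SpeciesDataset, StudyData

__all__ = ["PipelineParams", "SpeciesResult", "StudyResult",
           "run_species", "run_study", "evaluate_study"]


@dataclass(frozen=True)
class PipelineParams:
    """Declared defaults of every pipeline stage."""

    rrna_min_identity: float = 0.90
    rrna_min_cov: float = 0.80
    min_overlap: int = 40
    min_reads: int = 10
    min_orf_len: int = 10
    score_threshold: float = 10.0
    min_coverage: float = 0.9
    psm: msms.PsmConfig = field(default_factory=msms.PsmConfig)
    evalue_cutoff: float = 1.0


@dataclass
class SpeciesResult:
    species: str
    abbrev: str
    contigs: List[prep.Contig]
    support: Dict[str, int]
    total_mapped: int
    putative: List[scan.PutativeToxin]
    psms: List[msms.Psm]
    records: List[ToxinRecord]
    shared: int


@dataclass
class StudyResult:
    species_results: List[SpeciesResult]
    summary: SummaryTable

    @property
    def records_per_species(self) -> Dict[str, List[ToxinRecord]]:
        return {r.species: r.records for r in self.species_results}


def run_species(dataset: SpeciesDataset, library: Sequence[LibraryProfile],
                refdb: Sequence[FastaRecord],
                rrna_refs: Sequence[FastaRecord],
                prior_reads: Optional[Sequence[prep.Read]] = None,
                params: Optional[PipelineParams] = None) -> SpeciesResult:
    params = params or PipelineParams()

    # --- transcript preparation -------------------------------------------
    reads = prep.remove_rrna(dataset.reads, rrna_refs,
                             params.rrna_min_identity, params.rrna_min_cov)
    if prior_reads:
        reads = prep.remove_carryover(reads, prior_reads)
    unique = prep.dedup_identical(reads)
    contigs = prep.assemble(unique, min_overlap=params.min_overlap)
    support, total = prep.map_support(contigs, reads)
    if total > 0:
        prep.compute_rpkm(contigs, total)
    rpkm_map = {c.id: c.rpkm for c in contigs}

    # --- transcriptome route: profile scan on supported contigs -----------
    supported = prep.filter_support(contigs, params.min_reads)
    orfs = [o for c in supported
            for o in scan.six_frame_orfs(c, params.min_orf_len)]
    hits = scan.scan_library(library, orfs, params.score_threshold) \
        if library and orfs else []
    putative, _removed = scan.filter_putative(
        hits, support, params.min_reads, params.min_coverage, rpkm_map)

    # --- proteome route: spectra against all translated contigs -----------
    all_orfs = [o for c in contigs
                for o in scan.six_frame_orfs(c, params.min_orf_len)]
    spectra = [msms.Spectrum.from_mgf_dict(d) for d in dataset.spectra]
    psms = msms.search(spectra, [(o.id, o.peptide) for o in all_orfs],
                       params.psm)
    validated, _rej = msms.validate(psms, params.psm.min_cys,
                                    params.psm.min_snr_fraction)

    # --- merge evidence ----------------------------------------------------
    proteome_records = []
    seen = set()
    for i, psm in enumerate(validated):
        if psm.peptide in seen:
            continue
        seen.add(psm.peptide)
        proteome_records.append(ToxinRecord(
            id=f"{dataset.abbrev}_ms{i + 1}", species=dataset.species,
            mature=psm.peptide, proteome=True))
    transcriptome_records = []
    for i, put in enumerate(putative):
        transcriptome_records.append(ToxinRecord(
            id=f"{dataset.abbrev}_tr{i + 1}", species=dataset.species,
            mature=put.mature, transcriptome=True, rpkm=put.rpkm))
    records, shared = merge_evidence(proteome_records,
                                          transcriptome_records)
    records.sort(key=lambda r: r.id)

    # --- classification and ICK annotation ---------------------------------
    family_ick = {}
    for ref in refdb:
        if ref.family:
            family_ick[ref.family] = bool(ref.ick)
    for rec in records:
        result = classify_record(rec.mature, refdb, params.evalue_cutoff)
        rec.family = result if isinstance(result, str) else result.family
        rec.ick = annotate_ick(rec, family_ick)

    return SpeciesResult(
        species=dataset.species, abbrev=dataset.abbrev, contigs=contigs,
        support=support, total_mapped=total, putative=putative,
        psms=validated, records=records, shared=shared)


def run_study(study: StudyData,
              params: Optional[PipelineParams] = None,
              library: Optional[Sequence[LibraryProfile]] = None) -> StudyResult:
    params = params or PipelineParams()
    if library is None:
        library = build_library(study.reference_db)

    results: List[SpeciesResult] = []
    prior: Optional[Sequence[prep.Read]] = None
    for dataset in study.species:
        results.append(run_species(dataset, library, study.reference_db,
                                   study.rrna_refs, prior_reads=prior,
                                   params=params))
        prior = dataset.reads

    # Rational names, unique across the whole study.
    registry = NameRegistry()
    families = sorted({r.family for sr in results for r in sr.records
                       if r.family != UNCHARACTERIZED})
    class_no = {f: i + 1 for i, f in enumerate(families)}
    class_no[UNCHARACTERIZED] = len(families) + 1
    for sr in results:
        paralog: Dict[str, int] = {}
        for rec in sr.records:
            paralog[rec.family] = paralog.get(rec.family, 0) + 1
            rec.name = registry.assign(
                "U", class_no[rec.family], "venotoxin", sr.abbrev,
                paralog[rec.family])

    summary = summarize({sr.species: sr.records for sr in results})
    return StudyResult(species_results=results, summary=summary)


def evaluate_study(study: StudyData, result: StudyResult) -> Dict[str, float]:
    """Score a pipeline run against the generator's ground truth.

    recall            -- fraction of planted mature peptides recovered
                         exactly in their own species' record set.
    family_accuracy   -- among recovered records matching a planted mature,
                         fraction assigned the planted family.
    ick_errors        -- among those records, count of ICK flag mismatches.
    """
    per_species_records = result.records_per_species
    truth_by_species: Dict[str, Dict[str, Tuple[str, bool]]] = {}
    for ds in study.species:
        truth_by_species[ds.species] = {
            p.mature: (p.family_id, p.ick) for p in ds.precursors
        }

    planted = 0
    recovered = 0
    fam_total = 0
    fam_correct = 0
    ick_errors = 0
    for species, truth in truth_by_species.items():
        record_by_mature = {r.mature: r
                            for r in per_species_records.get(species, [])}
        for mature, (family, ick) in truth.items():
            planted += 1
            rec = record_by_mature.get(mature)
            if rec is None:
                continue
            recovered += 1
            fam_total += 1
            if rec.family == family:
                fam_correct += 1
            if rec.ick != ick:
                ick_errors += 1
    return {
        "planted": planted,
        "recovered": recovered,
        "recall": recovered / planted if planted else 0.0,
        "family_accuracy": fam_correct / fam_total if fam_total else 0.0,
        "ick_errors": ick_errors,
    }
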