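"""Ground-truthed synthetic venom-gland datasets.

Emulates the statistical structure a venom proteotranscriptomic pipeline
assumes: toxin precursors with the canonical signal / propeptide / mature
architecture, a labelled cysteine-rich reference database with several
divergent families, short single-end reads with substitution errors, rRNA
background, run-to-run carry-over contamination, and noisy singly-charged
b/y fragmentation spectra of reduced (unalkylated) mature peptides.

Every operation takes an explicit ``numpy.random.Generator``; a fixed seed
fully determines every output byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .prep import Read
from .scaffold import CysteineScaffold, matches_knottin_envelope, scaffold_of
from .seqio import FastaRecord

__all__ = [
    "ParameterError",
    "GeneratorConfig",
    "FamilySpec",
    "ToxinPrecursor",
    "default_config",
    "make_family_specs",
    "generate_precursor",
    "generate_reference_db",
    "generate_rrna_refs",
    "generate_reads",
    "generate_spectra",
    "write_truth",
    "read_truth",
    "truth_table",
    "generate_study",
    "SpeciesDataset",
    "StudyData",
    "DEFAULT_SPECIES",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# Hydrophobic residues used to bias signal-peptide composition.
HYDROPHOBIC = "AILMFVW"
_NON_CYS = [a for a in AMINO_ACIDS if a != "C"]
# Mature N-terminal residues preceding the first cysteine exclude basic
# residues: precursor processing cleaves after the last basic residue of the
# propeptide, so a basic residue there would itself be a processing site.
_MATURE_NPAD = [a for a in AMINO_ACIDS if a not in "CRK"]

# Standard codon table, one deterministic list of codons per amino acid.
_CODONS: Dict[str, List[str]] = {}
_STOPS = ("TAA", "TAG", "TGA")
_BASES = "TCAG"
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_TABLE):
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_codon)


class ParameterError(ValueError):
    """Raised when generator parameters are internally inconsistent."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the standing study conditions."""

    n_families: int = 6
    toxins_per_family: int = 5
    scaffolds: Tuple[CysteineScaffold, ...] = (
        CysteineScaffold(6, (6, 6, 0, 4, 8)),
        CysteineScaffold(6, (5, 8, 1, 6, 10)),
        CysteineScaffold(6, (4, 7, 2, 5, 6)),
        CysteineScaffold(4, (5, 7, 9)),
        CysteineScaffold(4, (3, 10, 4)),
        CysteineScaffold(6, (1, 5, 3, 4, 7)),
    )
    family_ick: Tuple[bool, ...] = (True, True, True, False, False, False)
    mature_len_range: Tuple[int, int] = (38, 46)
    signal_len_range: Tuple[int, int] = (18, 25)
    propeptide_len_range: Tuple[int, int] = (8, 16)
    within_family_identity: float = 0.8
    members_per_family: int = 5
    read_len: int = 150
    depth_mean: float = 20.0
    error_rate: float = 0.005
    rrna_fraction: float = 0.1
    carryover_fraction: float = 0.01
    spectrum_noise_peaks: int = 20
    n_spectra: int = 200
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("within_family_identity", "error_rate", "rrna_fraction",
                     "carryover_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.within_family_identity <= 1.0:
            raise ParameterError("within_family_identity must be in (0,1]")
        for name in ("mature_len_range", "signal_len_range", "propeptide_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ParameterError(f"{name} is empty: {(lo, hi)}")
        if len(self.scaffolds) < self.n_families:
            raise ParameterError("need one scaffold per family")
        if len(self.family_ick) < self.n_families:
            raise ParameterError("need one ICK label per family")


def default_config(**overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


@dataclass(frozen=True)
class FamilySpec:
    """One synthetic toxin family: scaffold, ICK label and founder mature peptide.

    All members of a family are substitution variants of the founder, so the
    scaffold (and mature length) is invariant within the family while the
    non-cysteine positions diverge.
    """

    family_id: str
    scaffold: CysteineScaffold
    ick: bool
    founder_mature: str
    signal_len_range: Tuple[int, int]
    propeptide_len_range: Tuple[int, int]
    within_family_identity: float


@dataclass(frozen=True)
class ToxinPrecursor:
    """Ground-truth precursor: signal + propeptide + mature, with its coding sequence."""

    id: str
    family_id: str
    signal: str
    propeptide: str
    mature: str
    cds: str
    ick: bool = False
    copy_number: int = 1

    @property
    def protein(self) -> str:
        return self.signal + self.propeptide + self.mature


def _founder_mature(scaffold: CysteineScaffold, mature_len_range: Tuple[int, int],
                    rng: np.random.Generator) -> str:
    lo, hi = mature_len_range
    if scaffold.span > hi:
        raise ParameterError(
            f"scaffold span {scaffold.span} exceeds mature length maximum {hi}"
        )
    length = int(rng.integers(max(lo, scaffold.span), hi + 1))
    pad_total = length - scaffold.span
    npad = int(rng.integers(0, min(pad_total, 4) + 1))
    cpad = pad_total - npad
    parts = ["".join(rng.choice(_MATURE_NPAD, size=npad))]
    for i in range(scaffold.n_cys):
        parts.append("C")
        if i < scaffold.n_cys - 1:
            parts.append("".join(rng.choice(_NON_CYS, size=scaffold.gaps[i])))
    parts.append("".join(rng.choice(_NON_CYS, size=cpad)))
    return "".join(parts)


def _mutate_mature(founder: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute non-cysteine positions at rate 1-identity, preserving the scaffold."""
    first_cys = founder.find("C")
    out = []
    for i, aa in enumerate(founder):
        if aa == "C" or rng.random() < identity:
            out.append(aa)
        else:
            pool = _MATURE_NPAD if (first_cys >= 0 and i < first_cys) else _NON_CYS
            choices = [a for a in pool if a != aa]
            out.append(str(rng.choice(choices)))
    return "".join(out)


def make_family_specs(config: GeneratorConfig, rng: np.random.Generator
                      ) -> List[FamilySpec]:
    specs = []
    for i in range(config.n_families):
        scaffold = config.scaffolds[i]
        founder = _founder_mature(scaffold, config.mature_len_range, rng)
        specs.append(FamilySpec(
            family_id=f"fam{i + 1}",
            scaffold=scaffold,
            ick=bool(config.family_ick[i]),
            founder_mature=founder,
            signal_len_range=config.signal_len_range,
            propeptide_len_range=config.propeptide_len_range,
            within_family_identity=config.within_family_identity,
        ))
    return specs


def _signal_peptide(len_range: Tuple[int, int], rng: np.random.Generator) -> str:
    n = int(rng.integers(len_range[0], len_range[1] + 1))
    n_hydro = int(np.ceil(0.7 * n))
    residues = list(rng.choice(list(HYDROPHOBIC), size=n_hydro))
    residues += list(rng.choice([a for a in _NON_CYS if a not in "RK"],
                                size=n - n_hydro))
    rng.shuffle(residues)
    return "".join(residues)


def _propeptide(len_range: Tuple[int, int], rng: np.random.Generator) -> str:
    n = int(rng.integers(len_range[0], len_range[1] + 1))
    body = "".join(rng.choice([a for a in _NON_CYS if a not in "RK"], size=n - 1))
    return body + "R"


def _encode(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS[aa][int(rng.integers(0, len(_CODONS[aa])))] for aa in protein
    ]
    codons.append(_STOPS[int(rng.integers(0, len(_STOPS)))])
    return "".join(codons)


def generate_precursor(family_spec: FamilySpec, rng: np.random.Generator,
                       precursor_id: Optional[str] = None) -> ToxinPrecursor:
    """Draw one precursor from a family: founder-derived mature, fresh signal/pro."""
    mature = _mutate_mature(family_spec.founder_mature,
                            family_spec.within_family_identity, rng)
    if scaffold_of(mature) != family_spec.scaffold:
        raise AssertionError("mutation must preserve the family scaffold")
    signal = _signal_peptide(family_spec.signal_len_range, rng)
    pro = _propeptide(family_spec.propeptide_len_range, rng)
    cds = _encode(signal + pro + mature, rng)
    copy = 1 + min(int(rng.poisson(2.0)), 7)
    return ToxinPrecursor(
        id=precursor_id or f"{family_spec.family_id}_tox",
        family_id=family_spec.family_id,
        signal=signal,
        propeptide=pro,
        mature=mature,
        cds=cds,
        ick=family_spec.ick,
        copy_number=copy,
    )


def generate_reference_db(families: Sequence[FamilySpec], rng: np.random.Generator,
                          members_per_family: int = 5) -> List[FastaRecord]:
    """Labelled mature-peptide reference database (one stand-in per toxin archive entry)."""
    if not families:
        raise ParameterError("at least one family is required")
    records = []
    for spec in families:
        for j in range(members_per_family):
            mature = _mutate_mature(spec.founder_mature,
                                    spec.within_family_identity, rng)
            records.append(FastaRecord(
                id=f"{spec.family_id}_ref{j + 1}",
                seq=mature,
                description=f"family={spec.family_id} ick={1 if spec.ick else 0}",
            ))
    return records


def generate_rrna_refs(rng: np.random.Generator, n: int = 3,
                       length: int = 1500) -> List[FastaRecord]:
    """Decoy ribosomal RNA references (random sequence; background, not toxin-like)."""
    return [
        FastaRecord(f"rrna{i + 1}",
                    "".join(rng.choice(list("ACGT"), size=length)), "decoy rRNA")
        for i in range(n)
    ]


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


_MIN_READ_LEN = 50


def _sample_read(template: str, read_len: int, error_rate: float,
                 rng: np.random.Generator) -> str:
    # Variable-length reads truncated at the template 3' end, so transcript
    # termini are covered (fixed-length windows systematically miss them).
    if len(template) <= read_len:
        seq = template
    else:
        min_len = min(_MIN_READ_LEN, read_len)
        start = int(rng.integers(0, len(template) - min_len + 1))
        seq = template[start:start + read_len]
    if rng.random() < 0.5:
        seq = _revcomp(seq)
    if error_rate > 0:
        chars = list(seq)
        for i in range(len(chars)):
            if rng.random() < error_rate:
                chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
        seq = "".join(chars)
    return seq


def generate_reads(precursors: Sequence[ToxinPrecursor], config: GeneratorConfig,
                   rng: np.random.Generator, run_id: str = "run1",
                   prior_reads: Optional[Sequence[Read]] = None,
                   rrna_refs: Optional[Sequence[FastaRecord]] = None,
                   n_reads: Optional[int] = None) -> List[Read]:
    """Simulate one sequencing run.

    Reads are drawn from transcripts in proportion to copy number x length so
    that expected coverage is ``depth_mean x copy_number``.  A
    ``carryover_fraction`` of reads are verbatim copies from ``prior_reads``
    and an ``rrna_fraction`` derive from the decoy rRNA references.
    """
    if n_reads is None:
        n_reads = int(round(sum(
            config.depth_mean * p.copy_number * len(p.cds) / config.read_len
            for p in precursors
        )))
    weights = np.array([p.copy_number * len(p.cds) for p in precursors], float)
    weights /= weights.sum()
    prior = list(prior_reads) if prior_reads else []
    rrna = list(rrna_refs) if rrna_refs else []
    reads: List[Read] = []
    for i in range(n_reads):
        rid = f"{run_id}_r{i:06d}"
        u = rng.random()
        if prior and u < config.carryover_fraction:
            src = prior[int(rng.integers(0, len(prior)))]
            seq = src.seq
        elif rrna and u < config.carryover_fraction + config.rrna_fraction:
            ref = rrna[int(rng.integers(0, len(rrna)))]
            seq = _sample_read(ref.seq, config.read_len, config.error_rate, rng)
        else:
            k = int(rng.choice(len(precursors), p=weights))
            seq = _sample_read(precursors[k].cds, config.read_len,
                               config.error_rate, rng)
        reads.append(Read(id=rid, seq=seq, qual="I" * len(seq), run_id=run_id))
    return reads


def generate_spectra(mature_peptides: Sequence[Tuple[str, str]],
                     config: GeneratorConfig, rng: np.random.Generator,
                     charge: int = 2) -> List[dict]:
    """Noisy fragmentation spectra of intact reduced mature peptides.

    Each spectrum contains every singly-charged monoisotopic b and y ion of
    its source peptide (cysteine at native mass: TCEP reduction without
    alkylation) plus ``spectrum_noise_peaks`` uniform noise peaks.  Returns
    MGF-style dictionaries with TITLE set to the spectrum id.
    """
    from .msms import PROTON, peptide_mass, theoretical_ions

    spectra = []
    for sid, pep in mature_peptides:
        bad = set(pep) - set(AMINO_ACIDS)
        if bad or not pep:
            raise ValueError(f"non-standard residues in {sid!r}: {sorted(bad)}")
        b_mz, y_mz = theoretical_ions(pep)
        signal = list(b_mz) + list(y_mz)
        intensities = list(rng.uniform(50.0, 150.0, size=len(signal)))
        if config.spectrum_noise_peaks:
            hi = max(signal) + 50.0
            noise_mz = rng.uniform(150.0, hi, size=config.spectrum_noise_peaks)
            noise_int = rng.uniform(1.0, 5.0, size=config.spectrum_noise_peaks)
            signal += list(noise_mz)
            intensities += list(noise_int)
        order = np.argsort(signal, kind="stable")
        mz = np.round(np.asarray(signal, float)[order], 5)
        inten = np.round(np.asarray(intensities, float)[order], 3)
        prec_mz = (peptide_mass(pep) + charge * PROTON) / charge
        spectra.append({
            "m/z array": mz,
            "intensity array": inten,
            "params": {
                "title": sid,
                "pepmass": (round(prec_mz, 5),),
                "charge": [charge],
            },
        })
    return spectra


def truth_table(precursors: Sequence[ToxinPrecursor]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": p.id,
                "family_id": p.family_id,
                "mature": p.mature,
                "expected_ick": int(p.ick),
                "copy_number": int(p.copy_number),
            }
            for p in precursors
        ],
        columns=["id", "family_id", "mature", "expected_ick", "copy_number"],
    )


def write_truth(precursors: Sequence[ToxinPrecursor], path) -> None:
    truth_table(precursors).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={
        "id": str, "family_id": str, "mature": str,
        "expected_ick": int, "copy_number": int,
    })


DEFAULT_SPECIES: Tuple[Tuple[str, str], ...] = (
    ("Pseudospider alpha", "Pa"),
    ("Pseudospider beta", "Pb"),
    ("Pseudospider gamma", "Pg"),
    ("Pseudospider delta", "Pd"),
)


@dataclass
class SpeciesDataset:
    species: str
    abbrev: str
    precursors: List[ToxinPrecursor]
    reads: List[Read]
    spectra: List[dict]


@dataclass
class StudyData:
    """A full synthetic study: shared reference DB plus per-species datasets."""

    config: GeneratorConfig
    family_specs: List[FamilySpec]
    reference_db: List[FastaRecord]
    rrna_refs: List[FastaRecord]
    species: List[SpeciesDataset]

    @property
    def all_precursors(self) -> List[ToxinPrecursor]:
        return [p for ds in self.species for p in ds.precursors]

    @property
    def truth(self) -> pd.DataFrame:
        return truth_table(self.all_precursors)


def generate_study(config: Optional[GeneratorConfig] = None,
                   species: Sequence[Tuple[str, str]] = DEFAULT_SPECIES,
                   ) -> StudyData:
    """Generate the default multi-species study.

    Precursors (``n_families x toxins_per_family``) are dealt round-robin
    across the pseudo-species; each species gets its own sequencing run, with
    the previous species' run acting as the carry-over source, and a share of
    the MS/MS spectra cycling over its mature peptides.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    specs = make_family_specs(config, rng)
    reference_db = generate_reference_db(specs, rng, config.members_per_family)
    rrna_refs = generate_rrna_refs(rng)

    precursors: List[ToxinPrecursor] = []
    for spec in specs:
        for j in range(config.toxins_per_family):
            precursors.append(generate_precursor(
                spec, rng, precursor_id=f"{spec.family_id}_tox{j + 1}"))

    n_sp = len(species)
    per_species: List[List[ToxinPrecursor]] = [[] for _ in range(n_sp)]
    for i, p in enumerate(precursors):
        per_species[i % n_sp].append(p)

    datasets: List[SpeciesDataset] = []
    prior: Optional[List[Read]] = None
    total = len(precursors)
    for s, (name, abbrev) in enumerate(species):
        mine = per_species[s]
        reads = generate_reads(mine, config, rng, run_id=f"run_{abbrev}",
                               prior_reads=prior, rrna_refs=rrna_refs)
        n_spec = int(round(config.n_spectra * len(mine) / total))
        targets = [(f"{abbrev}_scan{i + 1:04d}", mine[i % len(mine)].mature)
                   for i in range(n_spec)]
        spectra = generate_spectra(targets, config, rng)
        datasets.append(SpeciesDataset(name, abbrev, mine, reads, spectra))
        prior = reads
    return StudyData(config, specs, reference_db, rrna_refs, datasets)
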