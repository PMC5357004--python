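# Methods

This note documents the models and procedures implemented in `venomscan`,
the parameters that matter and why their defaults are what they are, what
the synthetic data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Pipeline model

The pipeline assumes the standard venom peptide gene model: a precursor of
signal peptide + propeptide + mature domain, of which only the mature
peptide is secreted, with proteolytic processing after a basic residue
(R/K) at the propeptide C-terminus. Classification rests on the cysteine
scaffold — cysteine count plus inter-cysteine spacings of the ungapped
mature sequence — as a proxy for disulfide architecture. True connectivity
is not observable from sequence; the ICK flag is therefore an inference
(family-label propagation and/or a spacing envelope), and the reported
connectivity (1,4),(2,5),(3,6) is the presumed knottin pairing of the
first six cysteines.

### Read cleaning

- **rRNA removal**: a read is dropped when it aligns to any reference rRNA
  (either strand) at ≥ 90 % identity. A shared 12-mer prescreens; a banded
  infix edit-distance alignment (edlib, whole read against the reference)
  verifies, so read coverage of an accepted alignment is complete by
  construction. Defaults (0.90 identity / 0.80 coverage) are declared
  constants.
- **Deduplication** keeps the first occurrence of each identical read
  sequence (same-strand exact equality).
- **Carry-over removal** drops reads exactly equal — as-is or
  reverse-complemented — to any read of the designated previous run.
  "Identical after orientation normalisation" is the strictest practical
  reading of cross-run decontamination by alignment.

### Assembly (stand-in) and quantification

A production de novo assembler is out of scope; contigs may be supplied
directly. The built-in stand-in:

1. **Greedy exact-overlap merging.** Unique read sequences are processed
   in descending length, then lexicographic order. Fragments exactly
   contained in a longer fragment (either strand) are absorbed. Candidate
   suffix→prefix overlaps ≥ `min_overlap` (default 40 nt) are collected for
   both orientations via prefix hashing and accepted greedily (longest
   first, deterministic tie-break by fragment index), with each fragment
   used in one orientation, each chain end used once, and no cycles.
2. **Consensus polishing.** Each contig position takes the majority base
   over all reads anchored to it by an exact 21-mer (ungapped placement;
   the error model is substitution-only). At 20× depth and 0.5 %
   substitution error, unpolished greedy chains carry one or two errors per
   contig — exactly the noise a consensus assembler removes — and polishing
   restores near-exact contigs. Polished contigs contained in a longer
   contig (either strand) are removed.

**Support** counts a read for a contig iff the read is an exact substring
(either strand); ties go to the longest contig, then the lexicographically
smallest id, so redundant short contigs collect no support and are removed
by the ≥ 10-read filter (boundary kept: support 10 passes, 9 fails).
Support is counted on the cleaned but *not* deduplicated read set.
**RPKM** is 10⁹·C/(N·L) with N = total mapped reads; the filter and the
scan operate on supported contigs, while the spectrum search uses all
contigs (low-abundance transcripts are still legitimate MS/MS targets).

### Profile library

- **Clustering**: single-linkage over pairs whose best local alignment
  (BLOSUM62, gap open −11 / extend −1) reaches 35 % identity over ≥ 80 %
  of the shorter sequence — standard sequence-family clustering defaults.
- **Alignment**: progressive profile–profile Gotoh (affine gaps, open −10 /
  extend −1, average-of-pairs BLOSUM62 column scores) over a UPGMA guide
  tree built from pairwise global alignment scores; all ties break
  lexicographically by id, so the MSA is deterministic.
- **Scaffold splitting**: an alignment is homogeneous iff every row has
  cysteines in exactly the same columns (the strictest reading of "same
  number, same spacing" on an alignment). Heterogeneous alignments are
  split by ungapped scaffold signature, realigned and re-tested; a group
  with a uniform signature that still fails (aligner placed C against
  non-C) is bisected by sorted id, guaranteeing termination. Singletons are
  homogeneous by construction.
- **Training**: alignment columns with gap fraction < 0.5 become match
  states. Emissions are Laplace-smoothed counts,
  (count + α)/(residues + 20α) with α = 1; transitions among
  {match, insert, delete} are counted from each row's state path and
  smoothed the same way, so every distribution is strictly positive and
  sums to one. The background is uniform (1/20). Profiles inherit the
  majority family label and ICK flag of their member sequences; parts with
  fewer than 2 rows are skipped.

### Contig scanning

Six-frame translation yields all maximal stop-to-stop peptides ≥ 10
residues, with coordinates mapped to the forward strand. Each ORF is
aligned locally through each profile by Viterbi dynamic programming:

- Emissions score in bits against the background,
  log₂(e/bg).
- Transitions score against the most probable continuation from their
  source state, log₂(t/max(row)). The canonical match→match path is
  transition-free and every deviation (gap open/extend, insert) costs.
  This was chosen after rejecting two alternatives: raw log₂(t) makes even
  a perfectly matching residue net-negative (the smoothed M→M probability
  is ≤ 0.75, i.e. ≥ 0.4 bits of penalty per step), collapsing self-hits to
  a single state, while a fixed null-extension probability of 1/2 makes
  M→M transitions net-positive and lets arbitrary long peptides drift
  above any threshold.
- Entry and exit are free at any match state; the empty alignment scores
  0; the best cell is traced back to give the peptide span, the match-state
  span and the coverage (match states spanned / total).

Hits need ≥ 10 bits (declared default), and filtered records additionally
need ≥ 10 supporting reads, ≥ 90 % profile coverage (partial ORFs and
frameshift-bearing contigs fail here — frameshifts are removed, not
repaired), no ambiguous residues in the span, ≥ 2 cysteines in the
predicted mature, and a mature cysteine count equal to the profile's
match-state consensus. The last rule is the scaffold logic of the library
applied at scan time: profiles are scaffold-homogeneous, so a hit whose
cysteine pattern disagrees with its own profile (typically an
antisense-frame "shadow" ORF of a real toxin transcript, which retains
enough compositional signal to score 10–15 bits) is spurious.

**Mature-peptide prediction**: cleavage after the last basic residue (R/K)
preceding the first cysteine of the matched span; the mature domain runs to
the ORF's C-terminus (toxin precursors end with the mature domain). If no
basic residue precedes the span, the span start is used.

### Spectrum matching

No enzymatic digestion is modelled: the venom is analysed intact after
TCEP reduction without alkylation, so candidates are whole ORF peptides
and their prefixes/suffixes whose monoisotopic mass lies within 10 ppm of
the precursor, and cysteine is at native mass with no modifications.
Theoretical fragments are singly-charged monoisotopic b₁..b₍n₋₁₎ and
y₁..y₍n₋₁₎ ions. The hyperscore is
log₁₀(Σ matched intensities · n_b! · n_y!), with each observed peak
matched to at most one theoretical ion (nearest within ±0.02 Da) and a
−∞ sentinel when nothing matches.

The expectation value fits log₁₀(survival count) against score linearly
over the upper half of the distinct candidate scores, **excluding the
single best score** (three or more distinct values required): the e-value
of a genuine hit must be judged against the distribution of the remaining
candidates — including the top score anchors its own survival at 1 and
pins every e-value near 1. Thin candidate sets are padded to 10 with
deterministic residue permutations (seeded from a hash of the spectrum id).
Degenerate fits (all scores equal, or non-negative slope) return 1.0.
Validation retains PSMs with ≥ 2 cysteines, no stop symbol, and a matched
intensity fraction ≥ 0.2 of the spectrum total (an automated stand-in for
manual signal-to-noise inspection; the 0.2 constant is declared, not
fitted).

### Classification, ICK annotation, naming, reporting

Records from both routes merge on identical mature sequence within a
species (idempotent, commutative; the shared count is reported). Each
record is classified by its best local-alignment hit against the labelled
reference database under BLOSUM62 (−11/−1); significance uses the
Karlin–Altschul form E = K·m·n·e^(−λS) with gapped-BLOSUM62 constants
λ = 0.267, K = 0.041 and n = total database length. Hits with e-value ≥ 1
leave the record "uncharacterized"; ties break by e-value, then bitscore,
then reference id. Alignment-score parity with BLAST is not claimed —
ranking fidelity is what the tests assert.

A record is flagged ICK when it has ≥ 6 cysteines and either its family is
ICK-labelled or its first six cysteines fit the knottin spacing envelope
C-X{3,10}-C-X{3,12}-C-X{0,7}-C-X{1,12}-C-X{1,15}-C (declared bounds,
configurable). Fewer than six cysteines never flag, regardless of family
label, since the motif needs three disulfides.

Names follow the rational scheme
`<descriptor><class>-<stem>-<species><paralog><isoform>` (e.g.
`U1-venotoxin-Pa5`); a registry bumps the paralog number on collision, so
names are injective within a run. Summary tables count, per species:
MS/MS-validated peptides (split into homology-classified and
uncharacterized), HMM-retrieved putative toxins, sequences shared by both
routes, the non-redundant total, ICK count, distinct ICK families, and the
ICK percentage rounded half-up to an integer; the total row is the column
sum, with the percentage recomputed from the totals (a percentage does not
add).

## Synthetic data generator

The generator is first-class, tested code that defines the conditions
under which the pipeline is evaluated:

- **Precursors**: per family, a founder mature sequence with a fixed
  cysteine scaffold and length; members are substitution variants at
  non-cysteine positions (within-family identity 0.8). Residues before the
  first cysteine exclude R/K — a basic residue there would itself be a
  processing site — which is what makes the R/K cleavage rule
  well-defined. Signal peptides are 18–25 residues at ≥ 60 % hydrophobic
  (actually sampled at 70 %); propeptides are 8–16 residues ending in R;
  signal and propeptide are cysteine-free. Coding sequences use uniformly
  random synonymous codons and a random stop.
- **Default families**: six scaffolds — three ICK
  (C6:6-6-0-4-8, C6:5-8-1-6-10, C6:4-7-2-5-6, all inside the knottin
  envelope), two 4-cysteine and one 6-cysteine scaffold whose first gap
  (1) violates the envelope, so family labels and envelope agree with the
  planted truth by construction.
- **Reads**: per-transcript read counts proportional to copy number ×
  length at 20× mean depth; reads are variable-length (up to 150 nt,
  minimum 50, truncated at the transcript 3′ end — fixed-length windows
  systematically under-cover transcript termini), strand-random, with
  substitution errors at 0.5 % per base. A configurable fraction of reads
  (default 10 %) derives from decoy rRNA references and a fraction
  (default 1 %) is copied verbatim from the previous run to emulate
  carry-over.
- **Spectra**: every singly-charged b/y ion of the mature peptide at
  uniform intensity 50–150, plus (default) 20 uniform noise peaks at
  intensity 1–5; precursor at charge 2. 200 spectra per study, dealt to
  species proportionally and cycling over their matures.
- **Determinism**: one `numpy` Generator seeded from the config drives
  everything; identical configs give byte-identical FASTA/FASTQ/MGF/TSV.

**What it does not emulate** — and hence what passing tests do not show
about real data: indels and homopolymer errors (an indel mode exists only
to exercise the frameshift filter), realistic quality scores, chimeric
reads, isoform splicing, length variation within a toxin family,
post-translational modifications (amidation, pyroglutamate,
hydroxyproline), co-eluting peptides, multiply-charged fragments, and
isotope envelopes. Recovery rates measured here are upper bounds for real
venomics data.

## Problem sizes and runtimes

The default study — 30 precursors across 6 families and 4 pseudo-species,
~700–1100 reads and ~50 spectra per species — runs end to end in roughly
10 s on one CPU; the full test suite takes under a minute, and the
acceptance script (default study + an error-free replicate of 18
precursors) under 30 s. These sizes were chosen so that the full
grid of unit, property and end-to-end tests runs comfortably in an
interactive workflow.

## Known limitations

- The greedy assembler is adequate only for the substitution-only,
  moderate-depth synthetic regime; it has no repeat resolution, no
  scaffolding, and exact-substring support counting undercounts
  error-bearing reads (about half the reads at 0.5 % error never map).
- Contigs truncated before the stop codon yield prefix-mature records;
  these merge away only if the full-length form is also recovered.
- e-value calibration is relative (ranking within a candidate set), not
  an absolute false-discovery control; no target-decoy FDR is computed.
- Classification identity/e-value use one declared constant set; scores
  are not interchangeable with BLAST output.
- ICK annotation is sequence-level inference; a peptide satisfying the
  envelope with different connectivity would be mislabelled.
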