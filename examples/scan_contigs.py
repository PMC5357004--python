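"""Transcriptome route: clean reads, assemble, and scan contigs for toxins.

Runs one pseudo-species through rRNA removal, deduplication, greedy
assembly with consensus polishing, support counting, and the profile-HMM
scan with the quality filters (>= 10 reads, >= 90% profile coverage,
cysteine-pattern congruence).
"""

from venomscan import (assemble, build_library, compute_rpkm, dedup_identical,
                       filter_support, generate_study, map_support,
                       remove_rrna, scan_library, six_frame_orfs,
                       filter_putative)

study = generate_study()
library = build_library(study.reference_db)
ds = study.species[0]

reads = remove_rrna(ds.reads, study.rrna_refs)
print(f"{len(ds.reads)} reads, {len(reads)} after rRNA removal")
unique = dedup_identical(reads)
contigs = assemble(unique, min_overlap=40)
support, total = map_support(contigs, reads)
compute_rpkm(contigs, total)
print(f"{len(contigs)} contigs, {total} reads mapped")

supported = filter_support(contigs, min_reads=10)
orfs = [o for c in supported for o in six_frame_orfs(c)]
hits = scan_library(library, orfs, score_threshold=10.0)
kept, removed = filter_putative(hits, support, min_reads=10,
                                min_coverage=0.9,
                                rpkm_by_contig={c.id: c.rpkm for c in contigs})

print(f"{len(orfs)} ORFs scanned, {len(kept)} putative toxins kept, "
      f"{len(removed)} best hits filtered out\n")
for p in kept:
    print(f"{p.contig_id:10s} {p.family_id:6s} score={p.score:6.1f} bits "
          f"coverage={p.coverage:.2f} support={p.support:3d} "
          f"rpkm={p.rpkm:9.0f}  mature={p.mature}")
# Each kept record's mature peptide is predicted from precursor processing:
# cleavage after the last basic residue preceding the matched cysteine span.
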