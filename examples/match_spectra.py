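"""Proteome route: match venom MS/MS spectra against translated contigs.

Intact (undigested, TCEP-reduced) mature peptides are identified by
hyperscore + survival-fit e-value against candidates drawn from six-frame
ORFs of the assembled contigs, then validated (>= 2 Cys, no stops,
matched-intensity >= 20% of the spectrum).
"""

from venomscan import (Spectrum, assemble, dedup_identical, generate_study,
                       remove_rrna, search, six_frame_orfs, validate)

study = generate_study()
ds = study.species[0]

reads = dedup_identical(remove_rrna(ds.reads, study.rrna_refs))
contigs = assemble(reads, min_overlap=40)
orfs = [o for c in contigs for o in six_frame_orfs(c)]
spectra = [Spectrum.from_mgf_dict(d) for d in ds.spectra]

psms = search(spectra, [(o.id, o.peptide) for o in orfs])
kept, rejected = validate(psms)

print(f"{len(spectra)} spectra, {len(psms)} PSMs under e-value < 1, "
      f"{len(kept)} validated")
planted = {p.mature for p in ds.precursors}
for psm in kept[:5]:
    truth = "planted" if psm.peptide in planted else "NOT planted"
    print(f"{psm.spectrum_id}: hyperscore={psm.hyperscore:6.1f} "
          f"e-value={psm.evalue:8.2e} b/y={psm.n_b_matched}/"
          f"{psm.n_y_matched}  [{truth}]")
exact = sum(1 for p in kept if p.peptide in planted)
print(f"\n{exact}/{len(kept)} validated PSMs are exactly the planted "
      f"mature peptide that generated the spectrum")
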