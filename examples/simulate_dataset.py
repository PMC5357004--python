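"""Generate the default ground-truthed synthetic venom study and look inside.

Thirty toxin precursors (six families, four pseudo-species) with reads,
spectra, a labelled reference database and a truth table.
"""

from venomscan import generate_study

study = generate_study()

print(f"families: {[s.family_id for s in study.family_specs]}")
print(f"reference DB: {len(study.reference_db)} labelled mature peptides")
for ds in study.species:
    print(f"{ds.species:22s} {len(ds.precursors):2d} precursors, "
          f"{len(ds.reads):5d} reads, {len(ds.spectra):3d} spectra")

p = study.species[0].precursors[0]
print(f"\nexample precursor {p.id} (family {p.family_id}, ICK={p.ick}):")
print(f"  signal     {p.signal}")
print(f"  propeptide {p.propeptide}   (ends in a basic cleavage residue)")
print(f"  mature     {p.mature}   ({p.mature.count('C')} cysteines)")
print(f"  copy number {p.copy_number} -> expected coverage "
      f"{study.config.depth_mean * p.copy_number:.0f}x")
# The truth table is what the acceptance metrics are scored against.
print(f"\ntruth table: {len(study.truth)} rows, "
      f"{int(study.truth.expected_ick.sum())} expected ICK toxins")
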