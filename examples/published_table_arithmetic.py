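"""Rebuild the cross-species summary from published per-species counts.

Feeding the four spiders' per-species discovery counts through the summary
builder reproduces the study-level totals (284 non-redundant sequences,
111 ICK toxins, 184 MS/MS-validated, 117 HMM-retrieved, 17 shared) and the
per-species ICK percentages (34/41/45/36), including the half-up percent
rounding.
"""

from venomscan.classify import SummaryTable

counts = {
    "H. davidbowie": dict(validated_msms=68, uncharacterized=50, homologous=17,
                          hmm_putative=29, hmm_in_venom=2, ick_count=32,
                          n_ick_families=7),
    "P. formosa": dict(validated_msms=103, uncharacterized=64, homologous=39,
                       hmm_putative=37, hmm_in_venom=14, ick_count=52,
                       n_ick_families=3),
    "V. fasciatus": dict(validated_msms=9, uncharacterized=8, homologous=1,
                         hmm_putative=41, hmm_in_venom=1, ick_count=22,
                         n_ick_families=4),
    "L. mactans": dict(validated_msms=4, uncharacterized=4, homologous=0,
                       hmm_putative=10, hmm_in_venom=0, ick_count=5,
                       n_ick_families=1),
}

summary = SummaryTable.from_counts(counts)
print(summary.to_text())
totals = summary.totals
print(f"\ntotal sequences {int(totals['total_sequences'])}, "
      f"ICK toxins {int(totals['ick_count'])}, "
      f"MS/MS validated {int(totals['validated_msms'])}, "
      f"HMM putative {int(totals['hmm_putative'])}, "
      f"shared {int(totals['hmm_in_venom'])}")
# total_sequences per species = validated_msms + hmm_putative - hmm_in_venom:
# the shared sequences are counted once in the non-redundant union.
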