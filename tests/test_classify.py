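import numpy as np
import pytest

from venomscan.classify import (ClassificationResult, NameRegistry,
                                SummaryTable, ToxinRecord, annotate_ick,
                                assign_name, classify, local_align,
                                merge_evidence, round_half_up, summarize,
                                UNCHARACTERIZED)
from venomscan.seqio import FastaRecord

from oracles import local_gotoh


class TestLocalAlign:
    def test_triple_cysteine_self_alignment(self):
        # Three C:C pairs at +9 each under BLOSUM62.
        score, identity, evalue = local_align("CCC", "CCC")
        assert score == 27.0
        assert identity == 1.0
        assert evalue < 1.0

    def test_dissimilar_pair_is_no_hit(self):
        score, identity, evalue = local_align("WWWW", "DDDD")
        assert score == 0.0 and identity == 0.0 and evalue == float("inf")

    def test_matches_bruteforce_dp_oracle(self):
        """Smith-Waterman scores equal an independent Gotoh DP on 200
        seeded random pairs of length <= 8."""
        rng = np.random.default_rng(99)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            a = "".join(rng.choice(alphabet, size=int(rng.integers(1, 9))))
            b = "".join(rng.choice(alphabet, size=int(rng.integers(1, 9))))
            expected = local_gotoh(a, b)
            score, _, _ = local_align(a, b)
            assert score == pytest.approx(expected)


class TestClassify:
    REFS = [
        FastaRecord("r1", "CKGWACNDCLPRGWKCEDSQCQCT", "family=famA ick=1"),
        FastaRecord("r2", "WHYMKEHHWNDKLHEWYKHQMMHW", "family=famB ick=0"),
    ]

    def test_self_hit_assigns_family(self):
        result = classify("CKGWACNDCLPRGWKCEDSQCQCT", self.REFS)
        assert isinstance(result, ClassificationResult)
        assert result.family == "famA" and result.best_ref_id == "r1"
        assert result.identity == 1.0

    def test_no_hit_below_cutoff(self):
        assert classify("GGGGG", self.REFS, evalue_cutoff=1e-6) == \
            UNCHARACTERIZED

    def test_zero_cutoff_always_uncharacterized(self):
        assert classify("CKGWACNDCLPRGWKCEDSQCQCT", self.REFS, 0.0) == \
            UNCHARACTERIZED

    def test_empty_refdb(self):
        assert classify("CCCC", []) == UNCHARACTERIZED

    def test_family_recovery_on_synthetic_db(self, default_study):
        """Members drawn from a family classify back to that family."""
        refs = default_study.reference_db
        rng = np.random.default_rng(0)
        from venomscan.simulate import generate_precursor
        for spec in default_study.family_specs:
            p = generate_precursor(spec, rng)
            result = classify(p.mature, refs)
            assert isinstance(result, ClassificationResult)
            assert result.family == spec.family_id


class TestAnnotateIck:
    LABELS = {"famA": True, "famB": False}

    def _rec(self, mature, family):
        return ToxinRecord("x", "sp", mature, proteome=True, family=family)

    def test_ick_family_label_propagates(self):
        rec = self._rec("ACAAAGCAAAACACAAAACAAAAAACA".replace("G", "C"), "famA")
        assert rec.mature.count("C") >= 6
        assert annotate_ick(rec, self.LABELS)

    def test_four_cysteine_non_ick_family_false(self):
        rec = self._rec("ACAAACAAAACAAAACA", "famB")
        assert not annotate_ick(rec, self.LABELS)

    def test_envelope_rescues_unclassified_knottin(self):
        # C-X6-C-X6-CC-X4-C-X8-C fits the knottin spacing envelope.
        mature = "AC" + "G" * 6 + "C" + "G" * 6 + "CC" + "G" * 4 + "C" + \
            "G" * 8 + "CA"
        rec = self._rec(mature, UNCHARACTERIZED)
        assert annotate_ick(rec, self.LABELS)

    def test_connectivity_reported_for_six_cysteines(self):
        from venomscan.scaffold import ick_connectivity, scaffold_of
        mature = "AC" + "G" * 6 + "C" + "G" * 6 + "CC" + "G" * 4 + "C" + \
            "G" * 8 + "CA"
        assert ick_connectivity(scaffold_of(mature)) == \
            ((1, 4), (2, 5), (3, 6))


class TestAssignName:
    @pytest.mark.parametrize("args, expected", [
        (("U", 1, "sparatoxin", "Hdb", 5, None), "U1-sparatoxin-Hdb5"),
        (("U", 8, "ctenitoxin", "Vf", 1, None), "U8-ctenitoxin-Vf1"),
        (("U", 2, "sicaritoxin", "Li", 1, "b"), "U2-sicaritoxin-Li1b"),
    ])
    def test_format(self, args, expected):
        assert assign_name(*args) == expected

    def test_collision_bumps_paralog(self):
        registry = NameRegistry()
        first = registry.assign("U", 1, "sparatoxin", "Hdb", 1)
        second = registry.assign("U", 1, "sparatoxin", "Hdb", 1)
        assert first == "U1-sparatoxin-Hdb1"
        assert second == "U1-sparatoxin-Hdb2"

    def test_invalid_descriptor(self):
        with pytest.raises(ValueError):
            assign_name("Z", 1, "sparatoxin", "Hdb", 1)

    def test_names_unique_across_run(self, default_run):
        _, result, _ = default_run
        names = [r.name for sr in result.species_results for r in sr.records]
        assert len(names) == len(set(names))
        assert all(n for n in names)


class TestMergeEvidence:
    def _rec(self, mature, proteome=False, transcriptome=False, sp="sp"):
        return ToxinRecord(mature[:4], sp, mature, proteome=proteome,
                           transcriptome=transcriptome)

    def test_shared_peptide_merges(self):
        records, shared = merge_evidence(
            [self._rec("ACDC", proteome=True)],
            [self._rec("ACDC", transcriptome=True)])
        assert len(records) == 1 and shared == 1
        assert records[0].proteome and records[0].transcriptome

    def test_disjoint_union(self):
        records, shared = merge_evidence(
            [self._rec("ACDC", proteome=True)],
            [self._rec("CWCW", transcriptome=True)])
        assert len(records) == 2 and shared == 0

    def test_idempotent_and_commutative(self):
        prot = [self._rec("ACDC", proteome=True)]
        tran = [self._rec("ACDC", transcriptome=True),
                self._rec("CWCW", transcriptome=True)]
        r1, s1 = merge_evidence(prot, tran)
        r2, s2 = merge_evidence(tran, prot)
        assert {(r.mature, r.proteome, r.transcriptome) for r in r1} == \
            {(r.mature, r.proteome, r.transcriptome) for r in r2}
        r3, s3 = merge_evidence(r1, [])
        assert s3 == s1
        assert {(r.mature, r.proteome, r.transcriptome) for r in r3} == \
            {(r.mature, r.proteome, r.transcriptome) for r in r1}

    def test_requires_evidence_flag(self):
        with pytest.raises(ValueError):
            ToxinRecord("x", "sp", "ACDC")


PAPER_COUNTS = {
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


class TestSummaryTable:
    def test_published_study_totals(self):
        table = SummaryTable.from_counts(PAPER_COUNTS).table
        totals = table.loc["Total"]
        assert totals["total_sequences"] == 284
        assert totals["ick_count"] == 111
        assert totals["validated_msms"] == 184
        assert totals["hmm_putative"] == 117
        assert totals["hmm_in_venom"] == 17

    def test_published_ick_percentages(self):
        table = SummaryTable.from_counts(PAPER_COUNTS).table
        assert table.loc["H. davidbowie", "ick_percent"] == 34
        assert table.loc["P. formosa", "ick_percent"] == 41
        assert table.loc["V. fasciatus", "ick_percent"] == 45
        assert table.loc["L. mactans", "ick_percent"] == 36

    def test_total_row_is_column_sum(self, default_run):
        _, result, _ = default_run
        table = result.summary.table
        for col in ("validated_msms", "hmm_putative", "total_sequences",
                    "ick_count"):
            species_sum = table.drop(index="Total")[col].sum()
            assert table.loc["Total", col] == species_sum

    def test_round_half_up(self):
        assert round_half_up(0.5) == 1
        assert round_half_up(33.4) == 33
        assert round_half_up(33.5) == 34


def test_summarize_counts_match_records(noiseless_run):
    study, result, _ = noiseless_run
    table = summarize(result.records_per_species).table
    for sr in result.species_results:
        row = table.loc[sr.species]
        assert row["total_sequences"] == len(sr.records)
        assert row["ick_count"] == sum(1 for r in sr.records if r.ick)
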