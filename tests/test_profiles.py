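import numpy as np
import pytest
from Bio import Align

from venomscan.msa import BLOSUM62, Msa, align_cluster, align_pair
from venomscan.profiles import (build_library, build_profile,
                                cluster_sequences, is_homogeneous,
                                load_library, save_library, split_msa)
from venomscan.seqio import FastaRecord
from venomscan.simulate import default_config, generate_reference_db, \
    make_family_specs

from oracles import random_msa


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        refs = [FastaRecord(f"s{i}", "CKGWACNDCLPRGWKCEDSQCQCT") for i in range(3)]
        assert len(cluster_sequences(refs)) == 1

    def test_single_linkage_transitivity(self):
        # A~B and B~C above threshold; A and C diverge further.
        a = "CKGWACNDCLPRGWKCEDSQCQCT"
        b = "CKGWACNDCLPRGWKCEDSQCQCA"
        c = "CKGWACNDCLPRGWKAEDSQAQCA"
        clusters = cluster_sequences([FastaRecord("a", a), FastaRecord("b", b),
                                      FastaRecord("c", c)])
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_unrelated_sequences_split(self):
        # Constructed pair with no meaningful local identity.
        a = "WWWHHHWWWHHHWWWHHHWWWHHHWWWHHH"
        b = "DEDEDEDEDEDEDEDEDEDEDEDEDEDEDE"
        from venomscan.msa import local_identity
        _, identity, _ = local_identity(a, b)
        assert identity < 0.2  # oracle: verified below threshold
        clusters = cluster_sequences([FastaRecord("a", a), FastaRecord("b", b)])
        assert len(clusters) == 2

    def test_order_invariance(self, rng):
        config = default_config()
        refs = generate_reference_db(make_family_specs(config, rng),
                                     np.random.default_rng(0))
        forward = cluster_sequences(refs)
        backward = cluster_sequences(list(reversed(refs)))
        as_sets = lambda cl: {frozenset(r.id for r in g) for g in cl}
        assert as_sets(forward) == as_sets(backward)


class TestAlignment:
    def test_single_sequence_identity(self):
        msa = align_cluster([("a", "ACDEFG")])
        assert msa.rows == [("a", "ACDEFG")] and msa.width == 6

    def test_identical_pair_gap_free(self):
        msa = align_cluster([("a", "ACDEFG"), ("b", "ACDEFG")])
        assert all(row == "ACDEFG" for _, row in msa.rows)

    def test_gap_opposite_unmatched_residue(self):
        msa = align_cluster([("a", "ACDC"), ("b", "ACC")])
        rows = dict(msa.rows)
        assert rows["a"] == "ACDC"
        assert rows["b"] == "AC-C"

    def test_pairwise_matches_biopython_oracle(self, rng):
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = BLOSUM62
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -1
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(30):
            a = "".join(rng.choice(alphabet, size=int(rng.integers(3, 12))))
            b = "".join(rng.choice(alphabet, size=int(rng.integers(3, 12))))
            score, row_a, row_b = align_pair(a, b)
            assert score == pytest.approx(aligner.score(a, b))
            assert row_a.replace("-", "") == a
            assert row_b.replace("-", "") == b

    def test_ungapping_recovers_input(self):
        seqs = [("a", "CKGWACNDC"), ("b", "CKGWCNDC"), ("c", "CKGWAACNDC")]
        msa = align_cluster(seqs)
        assert sorted(msa.ungapped()) == sorted(seqs)

    def test_empty_cluster_is_error(self):
        with pytest.raises(ValueError):
            align_cluster([])


class TestHomogeneity:
    def test_identical_rows_homogeneous(self):
        assert is_homogeneous(Msa([("a", "CAC"), ("b", "CAC")]))

    def test_extra_cysteine_breaks_homogeneity(self):
        assert not is_homogeneous(Msa([("a", "CAC"), ("b", "CCC")]))

    def test_same_count_different_columns_not_homogeneous(self):
        assert not is_homogeneous(Msa([("a", "CAC-"), ("b", "C-AC")]))


class TestSplitMsa:
    def test_homogeneous_returned_unchanged(self):
        msa = Msa([("a", "CAC"), ("b", "CAC")])
        parts = split_msa(msa)
        assert len(parts) == 1 and parts[0].rows == msa.rows

    def test_split_by_cysteine_count(self):
        msa = align_cluster([
            ("a", "CKGWACNDCAPRGWKCEDSQCQ"),
            ("b", "CKGWACNDCAPRGWKCEDSQAQ"),
            ("c", "CKGWACNDCAPRGWKCEDSQCQ"),
        ])
        parts = split_msa(msa)
        assert len(parts) == 2
        counts = sorted(len(p.rows) for p in parts)
        assert counts == [1, 2]

    def test_partition_and_homogeneity(self, rng):
        for _ in range(60):
            msa = random_msa(rng)
            parts = split_msa(msa)
            ids = sorted(rid for p in parts for rid, _ in p.rows)
            assert ids == sorted(rid for rid, _ in msa.rows)
            assert all(is_homogeneous(p) for p in parts)
            # splitting preserves the underlying sequences
            orig = dict(msa.ungapped())
            for p in parts:
                for rid, seq in p.ungapped():
                    assert seq == orig[rid]


class TestBuildProfile:
    def test_gap_free_width_equals_match_states(self):
        msa = Msa([("a", "ACDEF"), ("b", "ACDEF")])
        assert build_profile(msa).n_match == 5

    def test_laplace_emission_single_row(self):
        hmm = build_profile(Msa([("a", "CAC")]), pseudocount=1.0)
        c_index = "ACDEFGHIKLMNPQRSTVWY".index("C")
        assert hmm.match_emissions[0, c_index] == pytest.approx(2 / 21)

    def test_probability_normalisation(self):
        hmm = build_profile(Msa([("a", "CKGWAC"), ("b", "CKGW-C")]))
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0)
        assert np.allclose(hmm.transitions.sum(axis=2), 1.0)
        assert hmm.insert_emissions.sum() == pytest.approx(1.0)

    def test_rejects_heterogeneous_msa(self):
        with pytest.raises(ValueError):
            build_profile(Msa([("a", "CAC"), ("b", "CCC")]))


class TestBuildLibrary:
    def test_two_scaffold_distinct_families_two_profiles(self):
        config = default_config(n_families=2)
        refs = generate_reference_db(
            make_family_specs(config, np.random.default_rng(0))[:2],
            np.random.default_rng(1))
        library = build_library(refs)
        assert len(library) == 2
        assert sorted(p.family_id for p in library) == ["fam1", "fam2"]
        icks = {p.family_id: p.ick for p in library}
        assert icks == {"fam1": True, "fam2": True}

    def test_mixed_scaffold_family_splits_but_keeps_label(self):
        refs = [
            FastaRecord("a1", "ACKGWACNDCLPRGWKCEDSQCKCT", "family=famX ick=0"),
            FastaRecord("a2", "ACKGWACNDCLPRGWKCEDSQCKCA", "family=famX ick=0"),
            FastaRecord("a3", "AAKGWACNDALPRGWKCEDSQCKCT", "family=famX ick=0"),
            FastaRecord("a4", "AAKGWACNDALPRGWKCEDSQCKCA", "family=famX ick=0"),
        ]
        library = build_library(refs)
        assert len(library) == 2
        assert all(p.family_id == "famX" for p in library)

    def test_deterministic_for_fixed_input(self, default_study):
        lib1 = build_library(default_study.reference_db)
        lib2 = build_library(default_study.reference_db)
        assert [(p.profile_id, p.family_id, p.member_ids) for p in lib1] == \
            [(p.profile_id, p.family_id, p.member_ids) for p in lib2]
        for a, b in zip(lib1, lib2):
            assert np.array_equal(a.hmm.match_emissions, b.hmm.match_emissions)

    def test_library_json_roundtrip(self, tmp_path, default_library):
        path = tmp_path / "library.json"
        save_library(default_library, path)
        loaded = load_library(path)
        assert [(p.profile_id, p.family_id, p.ick) for p in loaded] == \
            [(p.profile_id, p.family_id, p.ick) for p in default_library]
        assert np.allclose(loaded[0].hmm.transitions,
                           default_library[0].hmm.transitions)

    def test_empty_refs_empty_library(self):
        assert build_library([]) == []
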