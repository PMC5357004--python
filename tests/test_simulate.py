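import io

import numpy as np
import pytest
from scipy import stats

import venomscan as v
from venomscan import seqio
from venomscan.scaffold import CysteineScaffold, scaffold_of
from venomscan.simulate import (GeneratorConfig, ParameterError,
                                generate_precursor, generate_reads,
                                generate_reference_db, generate_rrna_refs,
                                generate_spectra, make_family_specs,
                                read_truth, truth_table, write_truth)


def _specs(config, seed=0):
    return make_family_specs(config, np.random.default_rng(seed))


class TestPrecursors:
    def test_same_seed_same_precursor(self):
        config = v.default_config()
        spec = _specs(config)[0]
        p1 = generate_precursor(spec, np.random.default_rng(5))
        p2 = generate_precursor(spec, np.random.default_rng(5))
        assert p1 == p2

    def test_planted_scaffold(self):
        config = v.default_config(
            scaffolds=(CysteineScaffold(6, (6, 6, 0, 4, 8)),) * 6)
        for spec in _specs(config):
            p = generate_precursor(spec, np.random.default_rng(2))
            assert scaffold_of(p.mature) == CysteineScaffold(6, (6, 6, 0, 4, 8))

    def test_precursor_architecture(self):
        spec = _specs(v.default_config())[1]
        p = generate_precursor(spec, np.random.default_rng(3))
        assert p.propeptide[-1] in "RK"
        # translation of the cds equals the full precursor protein
        from Bio.Seq import Seq
        translated = str(Seq(p.cds).translate())
        assert translated == p.protein + "*"
        assert "*" not in translated[:-1]
        # signal is hydrophobic-biased
        hydro = sum(1 for aa in p.signal if aa in "AILMFVW")
        assert hydro / len(p.signal) >= 0.6

    def test_infeasible_scaffold_is_parameter_error(self):
        with pytest.raises(ParameterError):
            config = v.default_config(
                scaffolds=(CysteineScaffold(6, (10, 10, 10, 5, 5)),) * 6,
                mature_len_range=(15, 20))
            _specs(config)


class TestReferenceDb:
    def test_counts_and_labels(self):
        config = v.default_config(n_families=2)
        refs = generate_reference_db(_specs(config)[:2],
                                     np.random.default_rng(0),
                                     members_per_family=5)
        assert len(refs) == 10
        assert {r.family for r in refs} == {"fam1", "fam2"}

    def test_ick_family_members_have_six_cysteines(self):
        config = v.default_config()
        refs = generate_reference_db(_specs(config), np.random.default_rng(0))
        for r in refs:
            if r.ick:
                assert r.seq.count("C") >= 6

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        config = v.default_config()
        outs = []
        for _ in range(2):
            refs = generate_reference_db(_specs(config),
                                         np.random.default_rng(11))
            path = tmp_path / "refs.fa"
            seqio.write_fasta(refs, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]


class TestReads:
    def test_error_free_reads_are_substrings(self):
        config = v.default_config(error_rate=0.0, rrna_fraction=0.0,
                                  carryover_fraction=0.0, depth_mean=5.0)
        spec = _specs(config)[0]
        p = generate_precursor(spec, np.random.default_rng(1))
        reads = generate_reads([p], config, np.random.default_rng(2))
        from venomscan.prep import revcomp
        assert reads
        for r in reads:
            assert r.seq in p.cds or revcomp(r.seq) in p.cds

    def test_rrna_fraction_within_binomial_bounds(self):
        config = v.default_config(error_rate=0.0, rrna_fraction=0.1,
                                  carryover_fraction=0.0)
        rng = np.random.default_rng(3)
        spec = _specs(config)[0]
        p = generate_precursor(spec, rng)
        rrna = generate_rrna_refs(rng)
        reads = generate_reads([p], config, rng, rrna_refs=rrna, n_reads=1000)
        from venomscan.prep import revcomp
        rrna_seqs = [x.seq for x in rrna]
        n_rrna = sum(
            1 for r in reads
            if any(r.seq in s or revcomp(r.seq) in s for s in rrna_seqs))
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.1)
        assert lo <= n_rrna <= hi

    def test_no_carryover_when_fraction_zero(self):
        config = v.default_config(error_rate=0.0, rrna_fraction=0.0,
                                  carryover_fraction=0.0)
        rng = np.random.default_rng(4)
        specs = _specs(config)
        p1 = generate_precursor(specs[0], rng)
        p2 = generate_precursor(specs[1], rng)
        prior = generate_reads([p1], config, rng, run_id="run0")
        reads = generate_reads([p2], config, rng, run_id="run1",
                               prior_reads=prior)
        prior_seqs = {r.seq for r in prior}
        assert all(r.seq not in prior_seqs for r in reads)

    def test_carryover_reads_are_verbatim_copies(self):
        config = v.default_config(error_rate=0.0, rrna_fraction=0.0,
                                  carryover_fraction=0.5)
        rng = np.random.default_rng(5)
        specs = _specs(config)
        p1 = generate_precursor(specs[0], rng)
        p2 = generate_precursor(specs[1], rng)
        prior = generate_reads([p1], config, rng, run_id="run0",
                               n_reads=50)
        reads = generate_reads([p2], config, rng, run_id="run1",
                               prior_reads=prior, n_reads=200)
        prior_seqs = {r.seq for r in prior}
        n_copies = sum(1 for r in reads if r.seq in prior_seqs)
        lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.5)
        assert lo <= n_copies <= hi


class TestSpectra:
    def test_noiseless_ack_has_four_fragment_peaks(self):
        config = v.default_config(spectrum_noise_peaks=0)
        spectra = generate_spectra([("s1", "ACK")], config,
                                   np.random.default_rng(0))
        assert len(spectra[0]["m/z array"]) == 4  # b1, b2, y1, y2

    def test_y1_of_lysine(self):
        config = v.default_config(spectrum_noise_peaks=0)
        spectra = generate_spectra([("s1", "ACK")], config,
                                   np.random.default_rng(0))
        assert np.any(np.abs(spectra[0]["m/z array"] - 147.1128) < 1e-3)

    def test_same_seed_identical_mgf(self, tmp_path):
        config = v.default_config()
        outs = []
        for _ in range(2):
            spectra = generate_spectra([("s1", "ACDCK"), ("s2", "CWCK")],
                                       config, np.random.default_rng(9))
            path = tmp_path / "out.mgf"
            seqio.write_mgf(spectra, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_nonstandard_residue_rejected(self):
        config = v.default_config()
        with pytest.raises(ValueError):
            generate_spectra([("s1", "ACBZ")], config,
                             np.random.default_rng(0))


class TestTruthTable:
    def test_roundtrip(self, tmp_path):
        config = v.default_config()
        rng = np.random.default_rng(6)
        precursors = [generate_precursor(s, rng, precursor_id=f"p{i}")
                      for i, s in enumerate(_specs(config))]
        path = tmp_path / "truth.tsv"
        write_truth(precursors, path)
        table = read_truth(path)
        assert table.equals(truth_table(precursors))
        assert len(table) == len(precursors)

    def test_empty_is_header_only(self, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth([], path)
        assert read_truth(path).empty
        assert path.read_text().strip() == \
            "id\tfamily_id\tmature\texpected_ick\tcopy_number"


def test_study_generation_is_deterministic():
    s1 = v.generate_study()
    s2 = v.generate_study()
    assert s1.truth.equals(s2.truth)
    assert [r.seq for r in s1.species[0].reads] == \
        [r.seq for r in s2.species[0].reads]
    assert [r.seq for r in s1.reference_db] == [r.seq for r in s2.reference_db]


def test_truth_ick_flags_match_family_labels(default_study):
    truth = default_study.truth
    fam_ick = {s.family_id: s.ick for s in default_study.family_specs}
    for _, row in truth.iterrows():
        assert bool(row.expected_ick) == fam_ick[row.family_id]
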