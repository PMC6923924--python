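import numpy as np
import pandas as pd
import pytest

import deepshape as ds
from deepshape.analyze import (
    CRITable,
    SYNONYMOUS_FAMILIES,
    compare_cri_conditions,
    profile_pccs,
    uniform_baseline_profile,
)
from deepshape.mapping import build_alignments
from deepshape.simulate import GroundTruth, make_profiles, sample_ground_truth
from deepshape.transcriptome import CODONS, encode_codon


class TestLengthNormalized:
    def test_single_item(self):
        np.testing.assert_allclose(
            ds.length_normalized_abundance([7.0], [100.0]), [1e6]
        )

    def test_symmetry_and_formula(self):
        np.testing.assert_allclose(
            ds.length_normalized_abundance([10, 10], [100, 100]), [5e5, 5e5]
        )
        np.testing.assert_allclose(
            ds.length_normalized_abundance([10, 30], [100, 100]), [2.5e5, 7.5e5]
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            ds.length_normalized_abundance([0.0, 0.0], [10.0, 10.0])
        with pytest.raises(ValueError):
            ds.length_normalized_abundance([1.0], [0.0])


class TestTranslationEfficiency:
    def frame(self, ids, **cols):
        return pd.DataFrame({"transcript_id": ids, **cols})

    def test_equal_gives_unity(self):
        te = ds.translation_efficiency(
            self.frame(["A"], abundance=[5e5]), self.frame(["A"], tpm=[5e5])
        )
        assert te["te"].iloc[0] == 1.0

    def test_hand_example(self):
        te = ds.translation_efficiency(
            self.frame(["A", "B"], abundance=[4e5, 6e5]),
            self.frame(["A", "B"], tpm=[5e5, 5e5]),
        )
        np.testing.assert_allclose(te["te"], [0.8, 1.2])

    def test_zero_tpm_flagged_undefined(self):
        te = ds.translation_efficiency(
            self.frame(["A", "B"], abundance=[4e5, 6e5]),
            self.frame(["A", "B"], tpm=[0.0, 5e5]),
        )
        assert not te["te_defined"].iloc[0]
        assert np.isnan(te["te"].iloc[0])


class TestStalling:
    def test_uniform_profile_no_calls(self):
        assert len(ds.detect_stalling(np.ones(20)).positions) == 0

    def test_all_zero_no_calls(self):
        assert len(ds.detect_stalling(np.zeros(20)).positions) == 0

    def test_hand_example(self):
        calls = ds.detect_stalling(np.array([1, 1, 1, 1, 1, 7], dtype=float))
        assert np.isclose(calls.mu, 2.0)
        assert np.isclose(calls.sigma, np.sqrt(5.0))
        assert list(calls.positions) == [5]

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(sigma=1.2, size=200)
        a = ds.detect_stalling(x).positions
        b = ds.detect_stalling(42.0 * x).positions
        np.testing.assert_array_equal(a, b)


class TestCRI:
    def test_single_member_family_is_zero(self):
        codons = np.array([encode_codon("ATG"), encode_codon("TGG"), encode_codon("ATG")])
        x = np.array([1.0, 5.0, 3.0])
        cri = ds.compute_cri(x, codons)
        assert cri[encode_codon("ATG")] == 0.0
        assert cri[encode_codon("TGG")] == 0.0

    def test_equal_family_means_are_zero(self):
        codons = np.array([encode_codon("GCT"), encode_codon("GCC")])
        cri = ds.compute_cri(np.array([2.0, 2.0]), codons)
        assert cri[encode_codon("GCT")] == 0.0
        assert cri[encode_codon("GCC")] == 0.0

    def test_hand_example(self):
        codons = np.array(
            [encode_codon("GCT"), encode_codon("GCC"), encode_codon("GCT")]
        )
        cri = ds.compute_cri(np.array([1.0, 4.0, 1.0]), codons)
        np.testing.assert_allclose(cri[encode_codon("GCT")], -0.6)
        np.testing.assert_allclose(cri[encode_codon("GCC")], 0.6)

    def test_zero_density_family_undefined(self):
        codons = np.array([encode_codon("GCT"), encode_codon("GCC")])
        cri = ds.compute_cri(np.array([0.0, 0.0]), codons)
        assert np.isnan(cri[encode_codon("GCT")])

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        codons = rng.integers(0, 64, 90)
        x = rng.lognormal(size=90)
        a = ds.compute_cri(x, codons)
        b = ds.compute_cri(3.7 * x, codons)
        np.testing.assert_allclose(a, b, equal_nan=True)

    def test_families_partition_the_codons(self):
        members = sorted(j for fam in SYNONYMOUS_FAMILIES for j in fam)
        assert members == list(range(64))


class TestAggregateCRI:
    def small_setup(self, sigma=1.0, seed=2):
        config = ds.SimulationConfig(
            n_genes=25, isoforms_per_gene=(1, 1), rfm_codon_rate_sigma=sigma, seed=seed
        )
        txome = ds.generate_transcriptome(config)
        truth = GroundTruth(table=sample_ground_truth(txome, config).table)
        rates = make_profiles(txome, truth, config)
        profiles = [p * len(p) for p in truth.profiles]  # mean-1 normalized
        return txome, profiles, rates

    def test_single_transcript_summary_equals_per_transcript(self):
        txome, profiles, _ = self.small_setup()
        keep = [profiles[0]] + [None] * (len(txome) - 1)
        table = ds.aggregate_cri(
            keep, txome, np.full(len(txome), 100.0), np.full(len(txome), 100.0)
        )
        row = table.per_transcript.iloc[0]
        merged = table.summary.set_index("codon")["mean_cri"]
        for codon in CODONS:
            if np.isnan(row[codon]):
                assert np.isnan(merged[codon])
            else:
                assert np.isclose(row[codon], merged[codon])

    def test_filter_is_monotone(self):
        txome, profiles, _ = self.small_setup()
        rng = np.random.default_rng(3)
        r = rng.uniform(0, 100, len(txome))
        t = rng.uniform(0, 100, len(txome))
        n_prev = None
        for threshold in (5.0, 20.0, 50.0):
            table = ds.aggregate_cri(profiles, txome, r, t, min_abundance=threshold)
            n = table.summary["n_transcripts"].sum()
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_no_transcripts_passing_warns(self, caplog):
        txome, profiles, _ = self.small_setup()
        with caplog.at_level("WARNING"):
            table = ds.aggregate_cri(
                profiles, txome, np.zeros(len(txome)), np.zeros(len(txome))
            )
        assert table.per_transcript.empty

    def test_planted_slow_codon_has_positive_cri(self):
        txome, profiles, rates = self.small_setup(sigma=1.0, seed=4)
        table = ds.aggregate_cri(
            profiles, txome, np.full(len(txome), 100.0), np.full(len(txome), 100.0)
        )
        summary = table.summary.set_index("codon")["mean_cri"]
        # slowest codon within a multi-member family dwells longest
        multi = [fam for fam in SYNONYMOUS_FAMILIES if len(fam) > 1]
        slow_family = min(multi, key=lambda fam: rates[fam].min())
        slow_codon = CODONS[slow_family[int(np.argmin(rates[slow_family]))]]
        assert summary[slow_codon] > 0


class TestCompareConditions:
    def tables(self, shift_codon=None, delta=0.3, n=40):
        rng = np.random.default_rng(5)
        ids = [f"T{i}" for i in range(n)]
        base = pd.DataFrame(
            rng.normal(0, 0.1, size=(n, 64)), index=ids, columns=CODONS
        )
        other = base + rng.normal(0, 0.01, size=(n, 64))
        if shift_codon is not None:
            other[shift_codon] = other[shift_codon] + delta
        empty = pd.DataFrame({"codon": CODONS, "mean_cri": np.nan, "n_transcripts": 0})
        return CRITable(base, empty, "A"), CRITable(other, empty, "B")

    def test_identical_conditions_degenerate(self):
        a, _ = self.tables()
        res = compare_cri_conditions(a, a)
        assert (res["status"] == "degenerate").all()
        assert res["p_value"].isna().all()

    def test_swap_symmetry(self):
        a, b = self.tables(shift_codon="GCA")
        p_ab = compare_cri_conditions(a, b)["p_value"]
        p_ba = compare_cri_conditions(b, a)["p_value"]
        np.testing.assert_allclose(p_ab, p_ba)

    def test_planted_shift_has_smallest_q(self):
        a, b = self.tables(shift_codon="GCA")
        res = compare_cri_conditions(a, b).set_index("codon")
        assert res.loc["GCA", "q_value"] == res["q_value"].min()

    def test_too_few_pairs_flagged(self):
        a, b = self.tables()
        a.per_transcript.iloc[2:, a.per_transcript.columns.get_loc("TTT")] = np.nan
        res = compare_cri_conditions(a, b).set_index("codon")
        assert res.loc["TTT", "status"] == "too_few_pairs"


class TestEvaluate:
    def perfect_setup(self):
        txome = ds.Transcriptome(
            [
                ds.Transcript("A", "G", "ACG" * 30, 0, 90),
                ds.Transcript("B", "G", "ACT" * 30, 0, 90),
            ]
        )
        rng = np.random.default_rng(6)
        truth = [rng.poisson(3.0, 30).astype(float) for _ in range(2)]
        truth[0][5] = 20.0  # guarantee at least one stalling event
        per_read = []
        k = 0
        for i, prof in enumerate(truth):
            for j, c in enumerate(prof):
                for _ in range(int(c)):
                    per_read.append((f"r{k}", [(i, j)]))
                    k += 1
        aln = build_alignments(per_read)
        prof = ds.allocate_reads(aln, ds.initialize_uniform(txome), txome)
        return txome, truth, prof

    def test_perfect_estimates(self):
        txome, truth, prof = self.perfect_setup()
        counts = np.array([t.sum() for t in truth])
        m = ds.evaluate(counts, counts, prof, truth, txome.cds_lengths_nt())
        assert np.isclose(m["count_pcc"], 1.0)
        assert m["count_mse"] == 0.0
        assert m["stalling_sensitivity"] == 1.0
        assert m["stalling_precision"] == 1.0
        assert m["fraction_profile_pcc_gt_0.9"] == 1.0

    def test_profile_pcc_matches_hand_computation(self):
        txome = ds.Transcriptome([ds.Transcript("A", "G", "ACG" * 3, 0, 9)])
        aln = build_alignments([("r0", [(0, 0)]), ("r1", [(0, 1)]), ("r2", [(0, 1)])])
        prof = ds.allocate_reads(aln, ds.initialize_uniform(txome), txome)
        truth = [np.array([2.0, 1.0, 0.0])]
        pcc = profile_pccs(prof, truth)[0]
        expected = np.corrcoef([1, 2, 0], [2, 1, 0])[0, 1]
        assert np.isclose(pcc, expected)

    def test_constant_estimate_reported_nan(self):
        txome = ds.Transcriptome([ds.Transcript("A", "G", "ACG" * 3, 0, 9)])
        aln = build_alignments([(f"r{j}", [(0, j)]) for j in range(3)])
        prof = ds.allocate_reads(aln, ds.initialize_uniform(txome), txome)
        truth = [np.array([3.0, 1.0, 2.0])]
        assert np.isnan(profile_pccs(prof, truth)[0])


class TestUniformBaseline:
    def test_splits_equally(self):
        txome = ds.Transcriptome(
            [
                ds.Transcript("A", "G", "ACG" * 30, 0, 90),
                ds.Transcript("B", "G", "ACT" * 30, 0, 90),
            ]
        )
        aln = build_alignments([("r", [(0, 2), (1, 9)])])
        prof = uniform_baseline_profile(aln, txome)
        assert prof.profile(0)[2] == 0.5
        assert prof.profile(1)[9] == 0.5
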