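import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

import deepshape as ds
from deepshape.simulate import (
    GroundTruth,
    codon_rate_table,
    generate_footprints,
    make_profiles,
    rfm_steady_state,
    sample_ground_truth,
)

MILLION = 1_000_000.0


def flat_transcriptome(n, cds="ATGAAACCCGGGTTTACGTGGCAT" * 5):
    return ds.Transcriptome(
        [ds.Transcript(f"T{i}", f"G{i}", cds, 0, len(cds)) for i in range(n)]
    )


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ds.SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            ds.SimulationConfig(read_length=2)
        with pytest.raises(ValueError):
            ds.SimulationConfig(shared_exon_probability=1.5)


class TestGenerateTranscriptome:
    def test_isoforms_share_exon_verbatim(self):
        config = ds.SimulationConfig(
            n_genes=20, isoforms_per_gene=(2, 2), shared_exon_probability=1.0, seed=3
        )
        txome = ds.generate_transcriptome(config)
        for gene, tids in txome.genes.items():
            assert len(tids) == 2
            a, b = (txome[t].sequence for t in tids)
            # first exon is always retained: a long common prefix exists
            k = 60
            assert a[:k] == b[:k]

    def test_deterministic_given_seed(self):
        config = ds.SimulationConfig(n_genes=5, seed=11)
        t1 = ds.generate_transcriptome(config)
        t2 = ds.generate_transcriptome(config)
        assert [t.sequence for t in t1] == [t.sequence for t in t2]

    def test_transcript_count_within_range(self):
        config = ds.SimulationConfig(n_genes=100, isoforms_per_gene=(1, 3), seed=0)
        txome = ds.generate_transcriptome(config)
        assert 100 <= len(txome) <= 300

    def test_all_transcripts_valid(self):
        config = ds.SimulationConfig(n_genes=30, seed=5)
        for t in ds.generate_transcriptome(config):
            assert t.validate() is None


class TestGroundTruth:
    def test_normalizations(self):
        config = ds.SimulationConfig(n_genes=20, seed=2)
        txome = ds.generate_transcriptome(config)
        truth = sample_ground_truth(txome, config)
        t = truth.table
        assert np.isclose(t["tpm"].sum(), MILLION)
        assert np.isclose(t["ribo_abundance"].sum(), MILLION)
        np.testing.assert_allclose(
            t["te"], t["ribo_abundance"] / t["tpm"], rtol=1e-12
        )
        assert abs(t["ribo_read_count"].sum() - config.n_ribo_reads) <= len(txome) / 2

    def test_equal_te_gives_r_equal_t(self):
        config = ds.SimulationConfig(
            n_genes=20, te_lognormal_mu_sigma=(0.3, 0.0), seed=2
        )
        txome = ds.generate_transcriptome(config)
        truth = sample_ground_truth(txome, config)
        np.testing.assert_allclose(
            truth.table["ribo_abundance"], truth.table["tpm"], rtol=1e-9
        )

    def test_te_draws_are_lognormal(self):
        config = ds.SimulationConfig(te_lognormal_mu_sigma=(0.0, 1.0), seed=9)
        txome = flat_transcriptome(10_000)
        truth = sample_ground_truth(txome, config)
        logte = np.log(truth.table["te_target"])
        assert stats.kstest(logte, "norm", args=(0.0, 1.0)).pvalue > 0.01


class TestRFM:
    def test_single_site_closed_forms(self):
        # lam0(1-x) = lam1 x  =>  x = lam0/(lam0+lam1)
        assert np.isclose(rfm_steady_state([1.0, 1.0])[0], 0.5)
        assert np.isclose(rfm_steady_state([1.0, 3.0])[0], 0.25)

    def test_matches_ode_integration(self):
        rates = np.array([0.7, 1.3, 0.4, 2.0, 0.9, 1.1])
        x = rfm_steady_state(rates)

        def dxdt(_, y):
            yp = np.concatenate(([1.0], y, [0.0]))
            lam = rates
            inflow = lam[:-1] * yp[:-2] * (1 - yp[1:-1])
            inflow[0] = lam[0] * (1 - y[0])
            outflow = lam[1:] * y * (1 - yp[2:])
            return inflow - outflow

        sol = solve_ivp(
            dxdt, (0, 5000), np.full(5, 0.1), rtol=1e-10, atol=1e-12, method="LSODA"
        )
        np.testing.assert_allclose(x, sol.y[:, -1], atol=1e-6)

    def test_densities_in_open_interval_and_flux_constant(self):
        rates = np.array([0.5] + list(np.exp(np.random.default_rng(0).normal(0, 1, 50))))
        x = rfm_steady_state(rates)
        assert np.all((x > 0) & (x < 1))
        xp = np.concatenate((x[1:], [0.0]))
        flux = rates[1:] * x * (1 - xp)
        assert np.ptp(flux) < 1e-8

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            rfm_steady_state([1.0])
        with pytest.raises(ValueError):
            rfm_steady_state([1.0, -2.0])


class TestProfiles:
    def test_homogeneous_rates_near_uniform(self):
        config = ds.SimulationConfig(rfm_codon_rate_sigma=0.0, seed=1)
        txome = flat_transcriptome(1, cds="ATGAAACCCGGGTTTACGTGGCAT" * 38)
        assert txome.transcripts[0].n_codons == 304
        truth = GroundTruth(table=sample_ground_truth(txome, config).table)
        make_profiles(txome, truth, config)
        p = truth.profiles[0]
        tv = 0.5 * np.abs(p - 1.0 / len(p)).sum()
        assert tv < 0.05

    def test_identical_cds_identical_profiles(self):
        config = ds.SimulationConfig(seed=4)
        txome = flat_transcriptome(2)
        truth = GroundTruth(table=sample_ground_truth(txome, config).table)
        make_profiles(txome, truth, config)
        np.testing.assert_array_equal(truth.profiles[0], truth.profiles[1])

    def test_profiles_sum_to_one(self, small_sim):
        _, _, truth, _, _ = small_sim
        for p in truth.profiles:
            assert np.isclose(p.sum(), 1.0)


class TestFootprints:
    def test_reads_are_exact_substrings(self, small_sim):
        _, txome, _, reads, _ = small_sim
        rng = np.random.default_rng(0)
        for k in rng.integers(0, len(reads), 200):
            t = txome.transcripts[reads.true_transcript_index[k]]
            assert reads.sequences[k] in t.sequence

    def test_read_mass_conservation(self, small_sim):
        _, _, truth, reads, _ = small_sim
        total_counts = int(truth.table["ribo_read_count"].sum())
        assert len(reads) == len(reads.read_ids)
        assert len(reads) + reads.n_window_skipped == total_counts
        emitted = sum(int(p.sum()) for p in truth.read_profiles)
        assert emitted == len(reads)

    def test_psite_sampling_matches_profile(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 36))
        txome = ds.Transcriptome([ds.Transcript("T", "G", seq, 0, 30)])
        config = ds.SimulationConfig(
            n_ribo_reads=100_000, read_length=6, psite_offset=0, seed=5
        )
        profile = np.array([1, 2, 3, 4, 5, 5, 4, 3, 2, 1], dtype=float)
        profile /= profile.sum()
        table = sample_ground_truth(txome, config).table
        table.loc[0, "ribo_read_count"] = 100_000
        truth = GroundTruth(table=table, profiles=[profile])
        reads = generate_footprints(txome, truth, config)
        assert reads.n_window_skipped == 0
        freq = np.bincount(reads.true_codon, minlength=10) / len(reads)
        assert 0.5 * np.abs(freq - profile).sum() < 0.01

    def test_fastq_deterministic(self, tmp_path):
        config = ds.SimulationConfig(n_genes=5, n_ribo_reads=500, seed=13)
        out = []
        for name in ("a.fq", "b.fq"):
            _, _, reads = ds.simulate_dataset(config)
            reads.write_fastq(tmp_path / name)
            out.append((tmp_path / name).read_bytes())
        assert out[0] == out[1]

    def test_multimappable_fraction_substantial(self, small_sim):
        _, _, _, _, alignments = small_sim
        assert 1.0 - alignments.unique_mapping_fraction > 0.30

    def test_abundance_recomputable_from_counts(self, small_sim):
        _, txome, truth, _, _ = small_sim
        t = truth.table
        kept = t["ribo_read_count"].to_numpy() > 0
        r = ds.length_normalized_abundance(
            t["ribo_read_count"].to_numpy(), txome.cds_lengths_nt()
        )
        # counts are rounded, so agreement is to rounding error only
        np.testing.assert_allclose(
            r[kept], t["ribo_abundance"].to_numpy()[kept], rtol=0.05, atol=30.0
        )


class TestRnaSeqExport:
    def test_tpm_table_matches_truth(self, tmp_path, small_sim):
        _, _, truth, _, _ = small_sim
        path = tmp_path / "tpm.tsv"
        df = ds.generate_rnaseq_abundance(truth, path)
        assert np.isclose(df["tpm"].sum(), MILLION)
        np.testing.assert_array_equal(df["tpm"], truth.table["tpm"])
        import pandas as pd

        again = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(again["tpm"], df["tpm"])
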