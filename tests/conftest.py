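import numpy as np
import pytest

import deepshape as ds
from deepshape.analyze import uniform_baseline_profile


@pytest.fixture
def toy_transcriptome():
    """Two genes: one two-isoform gene sharing a 60-nt exon, one singleton."""
    shared = "ACGTGGCTAATCGGATCCTAGGCATCGATCGGATTACGCATGCATCGATCGGAATTCCGA"
    a = "ATG" + shared + "GGC" * 10 + "TAA"
    b = "ATG" + shared + "TTT" * 7 + "TAA"
    c = "ATGCATCATCATGGGTTTCCCAAATTTGGGCCCTAA"
    return ds.Transcriptome(
        [
            ds.Transcript("A", "G1", a, 0, len(a)),
            ds.Transcript("B", "G1", b, 0, len(b)),
            ds.Transcript("C", "G2", c, 0, len(c)),
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 30-gene synthetic dataset with mapping and truth, shared by tests."""
    config = ds.SimulationConfig(n_genes=30, n_ribo_reads=20_000, seed=7)
    transcriptome, truth, reads = ds.simulate_dataset(config)
    alignments = ds.map_reads_exact(
        reads, transcriptome, psite_offset=config.psite_offset, keep_read_ids=True
    )
    return config, transcriptome, truth, reads, alignments


@pytest.fixture(scope="session")
def desk_pipeline():
    """The desk-scale study fixture: full pipeline, all allocators.

    300 genes, 1-3 exon-sharing isoforms, 2x10^5 30-nt reads; exact
    mapping at the simulator's P-site offset; 200 abundance-only
    iterations; the joint abundance x shape loop warm-started from them;
    and the uniform split baseline.
    """
    config = ds.SimulationConfig(seed=1)
    transcriptome, truth, reads = ds.simulate_dataset(config)
    alignments = ds.map_reads_exact(
        reads, transcriptome, psite_offset=config.psite_offset
    )
    prime = ds.PrimeAllocator(n_iter=200).fit(alignments, transcriptome)
    deep = ds.DeepShapeAllocator(n_iter=10, warm_start=prime.r_, seed=0).fit(
        alignments, transcriptome
    )
    uniform = uniform_baseline_profile(alignments, transcriptome)
    true_counts = np.array([p.sum() for p in truth.read_profiles])
    lengths = transcriptome.cds_lengths_nt()
    metrics = {
        "prime": ds.evaluate(
            prime.read_counts_, true_counts, prime.profile_, truth.read_profiles, lengths
        ),
        "deepshape": ds.evaluate(
            deep.read_counts_, true_counts, deep.profile_, truth.read_profiles, lengths
        ),
        "uniform": ds.evaluate(
            uniform.transcript_mass(), true_counts, uniform, truth.read_profiles, lengths
        ),
    }
    return {
        "config": config,
        "transcriptome": transcriptome,
        "truth": truth,
        "reads": reads,
        "alignments": alignments,
        "prime": prime,
        "deep": deep,
        "uniform": uniform,
        "metrics": metrics,
    }
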