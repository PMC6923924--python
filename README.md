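# deepshape

Isoform-level ribosome abundance and codon-resolution ribosome profiles
from Ribo-seq data alone — no matched RNA-seq required.

## The problem

Ribosome profiling (Ribo-seq) sequences ~30-nt ribosome-protected mRNA
fragments; the pileup of their P-sites along a transcript reports where
ribosomes sit, codon by codon. But isoforms of a gene share exons, so a
large fraction of footprints map equally well to several transcripts. Any
transcript-level statement — which isoform is being translated, how
efficiently, where ribosomes stall on it — first requires allocating those
multi-mapped reads. Tools that borrow RNA-seq abundances for this are
biased whenever translation efficiency varies, which is precisely the
situation of interest.

This package allocates multi-mapped footprints iteratively from the
Ribo-seq data itself:

- **Abundance-only allocation** (`PrimeAllocator`). Starting from a
  uniform CDS-length-normalized ribosome abundance
  `r_i = (c_ri/l_ri) / Σ_k (c_rk/l_rk) × 10^6`, each iteration splits
  every read over its candidate transcripts in proportion to the current
  `r_i` and re-estimates the abundances from the allocated mass, until
  the fixed point.
- **Joint abundance × shape allocation** (`DeepShapeAllocator`). A small
  convolutional network — the *shape model* — is trained on the current
  allocation to predict the normalized ribosome density
  `x_ij = c_ij / Σ_j c_ij × l_i` at a codon from the 121-codon sequence
  window around it (60 codons of context each side). Reads are then
  allocated with weight `r_i × s_i(codon)`, where the per-transcript
  mean-1 instructive shape `s` lets sequence context arbitrate between
  candidate positions — including frame-shifted shared exons, where the
  two isoforms read the same nucleotides in different codon frames and
  genuinely differ in occupancy. The loop alternates allocate / retrain /
  re-estimate.

Downstream statistics: translation efficiency `TE = r_i / t_i` against
mRNA TPM; ribosome stalling calls (codons with normalized density strictly
above `μ + 2σ` of their transcript); and the **Codon Residence Index**
`CRI_ij = mean_x(codon j) / mean over j' in S_j of mean_x(j') − 1`, the
relative dwell of a codon versus its synonymous codons on the same
transcript (positive = slower), with paired Wilcoxon comparison across
conditions.

A fully ground-truthed synthetic pipeline (`simulate_dataset`) generates
multi-isoform transcriptomes with verbatim-shared exons, log-normal
expression and TE, ribosome-flow-model (RFM) codon occupancy profiles with
codon-identity dwell rates, and error-free 30-nt footprints with known
P-sites — the substrate for all validation.

## Worked example

```python
import numpy as np
import deepshape as ds

config = ds.SimulationConfig(n_genes=30, n_ribo_reads=20_000, seed=7)
transcriptome, truth, reads = ds.simulate_dataset(config)
alignments = ds.map_reads_exact(reads, transcriptome, psite_offset=12)
print(f"{alignments.n_reads} reads, "
      f"{1 - alignments.unique_mapping_fraction:.0%} multi-mapped")

prime = ds.PrimeAllocator(n_iter=200).fit(alignments, transcriptome)
true_counts = np.array([p.sum() for p in truth.read_profiles])
metrics = ds.evaluate(prime.read_counts_, true_counts, prime.profile_,
                      truth.read_profiles, transcriptome.cds_lengths_nt())
print(f"read-count PCC {metrics['count_pcc']:.4f}, "
      f"profiles with PCC>0.9: {metrics['fraction_profile_pcc_gt_0.9']:.0%}")
```

prints

```
19582 reads, 37% multi-mapped
read-count PCC 1.0000, profiles with PCC>0.9: 82%
```

i.e. on a 30-gene dataset where over a third of the footprints are ambiguous,
200 allocation iterations recover per-isoform read counts almost exactly,
and most per-codon profiles to high fidelity. Warm-starting the joint
allocator from these abundances (`DeepShapeAllocator(warm_start=prime.r_)`)
improves the profile metrics further; see `scripts/acceptance.py` for the
full comparison including the uniform-splitting baseline.

A command-line interface mirrors the library
(`deepshape simulate|map|prime|deepshape|analyze`); the annotation TSV
dialect is `transcript_id  gene_id  cds_start  cds_end` with 0-based
half-open CDS coordinates in transcript space (GTF with transcript-space
CDS features is also accepted).

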