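# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Coordinate conventions

Everything runs in transcript space, 0-based half-open. The P-site of a
footprint whose 5' end maps at nucleotide `p` is nucleotide `p + offset`
(default offset 12 nt, the standard distance from the 5' end of a ~30-nt
fragment to the peptidyl site; configurable, and a per-length offset table
can be emulated by mapping length-filtered batches separately). The codon
index is `(psite_nt − cds_start) // 3`. Reads whose P-site leaves the
`[cds_start, cds_end)` interval are excluded everywhere: abundances are
CDS-normalized densities and profiles are CDS codon vectors, so UTR mass
has no denominator to live in. Codons are encoded lexicographically over
A<C<G<T (AAA=0 … TTT=63); codons containing N, and positions outside the
CDS in context windows, carry the pad index 64, which one-hot encodes to
the zero vector.

## Allocation model

Reads with identical candidate sets are collapsed into equivalence
classes with a multiplicity; allocation is exactly per-read allocation
but linear in the number of distinct classes.

*Abundance-only* (the fast estimator): candidate weight is the current
CDS-length-normalized abundance `r_i`; a read's weights are normalized
over its candidate set, a zero-weight set falls back to a uniform split
(mass is always conserved), and abundances are re-estimated as
`r_i = (c_ri/l_ri)/Σ(c_rk/l_rk) × 10^6`. Iteration stops at `n_iter`
(default 200) or when the largest abundance change falls below 1e-8 of
10^6. Note the weight is the length-normalized density, not the raw
count: two transcripts tied by a shared read at equal density stay tied
regardless of their lengths.

*Joint abundance × shape*: candidate weight `r_i × s_i(codon)`. The
product is the minimal combination that reduces exactly to the
abundance-only rule when `s ≡ 1`, which is also the loop's initial state
and the tested reduction. Because `s` is renormalized to mean 1 per
transcript, it carries only within-transcript structure; abundance and
shape stay separately interpretable factors.

One deliberate stabilisation beyond the plain three-step loop: the
instructive shapes used for allocation are the *running average* of all
refit predictions so far (`shape_averaging`, on by default). Successive
refits differ in their resampled training sets, validation splits and
initialisations; feeding each refit's raw prediction straight back into
allocation lets that refit-to-refit variance accumulate through the
abundance estimates (in desk-scale experiments the read-count PCC decayed
from 0.996 to 0.977 over ten iterations and the profile gains evaporated),
while averaging makes the loop improve monotonically and plateau.
Disable it to recover the plain scheme.

## Shape model

A regressor from the 121-codon window (60 up, the codon, 60 down) to the
mean-1 normalized density `x_ij`. Architecture: one-hot 64-channel input,
three same-padding 1-D convolutions (32 filters, kernel 5, ReLU), pooling
over the window with *learned per-position weights*, one hidden dense
layer (64 units, ReLU), scalar output interpreted as `log x` and
exponentiated, so predictions are always positive. The pooling weights
are initialised with half their mass on the window centre and half spread
uniformly: dwell time is dominated by the codon in the P-site, and with
plain uniform average pooling the centre codon is 1/121 of the pooled
signal and its planted effect is unrecoverable at the training-set sizes
used here. The network is implemented directly in numpy (im2col
convolutions, manual backprop, Adam at lr 1e-3, batch 512, float32); at
this size a framework would add nothing but a dependency.

Training targets: all nonzero `x_ij` of the current allocation; log-scale
mean and population SD (`μ, σ`) computed; values outside `[μ−3σ, μ+3σ]`
in natural log discarded; that range split into 10 equal bins, each
resampled to `samples_per_bin` points (with replacement when short), so
rare very-high and very-low densities are not drowned out by the bulk.
`samples_per_bin` defaults to 2,000 (20,000 points per refit) at desk
scale. Loss is the mean squared difference of natural logs with both
sides clipped at 1e-8; the base is a pure rescaling of the objective, and
the clip makes zero/zero pairs contribute nothing.

Early stopping follows validation loss on a held-out fraction (10%,
fixed per fit by the seed), stopping when an epoch's validation loss
exceeds the previous epoch's by more than 5% relative and restoring the
best weights. The tolerance matters at this scale: with 20k samples an
epoch is ~35 Adam steps, so epoch-to-epoch validation noise during the
initial plateau would otherwise end training before the conv features
form. Each in-loop refit is a fresh model (capped at 25 epochs by
default) rather than a fine-tune of the previous one, so no optimizer
state couples consecutive iterations.

Evaluation mode: the pipeline always scores transcripts *densely* — one
conv pass over the padded transcript, then the pooling window slides —
which is ~two orders of magnitude cheaper than materialising one window
per codon and is also how in-loop training evaluates its samples, so
fitting and prediction see identical context semantics. The
(window-matrix → prediction) interface remains for the sklearn estimator
contract; the two modes agree exactly whenever the window's surroundings
are pad tokens and differ only in whether conv taps at a window's rim see
zeros or the true neighbouring codons.

## Synthetic data

The generator's defaults are the package's study conditions; every choice
below is fixed and seeds control all randomness.

* **Transcriptome**: 300 genes, 4–8 exon blocks of 90–300 nt, 1–3
  isoforms per gene. The first isoform concatenates all exons; others
  drop a random non-empty subset of internal exons, so isoforms share
  exons verbatim and short reads multi-map. Exon lengths are rounded to
  multiples of 3 with probability 0.8: most junctions preserve reading
  frame (as in real annotations), a minority shift it, creating isoform
  pairs whose true profiles genuinely differ on shared sequence. CDS
  spans the whole transcript, trimmed to whole codons.
* **Abundances**: gene expression log-normal (σ = 2.0 on the natural-log
  scale), isoform usage within a gene Dirichlet(α = 0.15). The sparse
  Dirichlet reproduces the strong single-isoform dominance of real
  transcriptomes; with it, the simulated truth reproduces the ~0.6
  mRNA-versus-ribosome abundance correlation reported for real data.
  TE is log-normal(0, 1); ribosome abundance `r_i ∝ t_i · TE_i`,
  normalized per million. Expected read counts are `∝ r_i · l_ri`.
* **Profiles**: ribosome flow model per transcript. Elongation rate at a
  codon is a transcriptome-wide per-codon-identity rate, log-normal with
  σ = 1.0 around unit median — a pause-site-like dynamic range that makes
  codon dwell statistics (CRI) recoverable. Initiation rate 0.005 puts
  every transcript in the initiation-limited regime (initiation, not
  elongation, is rate-limiting for most real mRNAs): site densities are
  low (`x_j ≈ J/λ_j`, so occupancy is inversely proportional to codon
  speed) with mild queueing upstream of strong pause codons, rather than
  system-spanning traffic jams.
* **Reads**: per transcript, `c_ri` P-site codons drawn from the profile;
  each read is the exact 30-nt substring starting 12 nt upstream of the
  P-site. Draws whose window would leave the transcript are skipped and
  counted — the first/last few codons are read-depleted, as in real
  libraries. No sequencing errors (the built-in mapper is exact-match;
  mismatch tolerance is the job of an external aligner whose SAM/BAM this
  package also accepts). RNA-seq is exported as the true TPM table: the
  TE analysis consumes abundances, so simulating RNA-seq reads would add
  noise without exercising any additional code path.

The generator records two truths per transcript: the RFM density (the
model's expectation) and the realised per-codon counts of the emitted
reads. Evaluation compares allocations against the latter — the
allocator's task is to put the *actual* reads back where they came from,
and at desk-scale depth (~1 read/codon) multinomial noise would bound the
PCC against the smooth RFM density far below 1 even for a perfect
allocator.

## RFM steady state

The steady state carries a constant flux `J` (initiation
`λ_0(1−x_1)`, bonds `λ_j x_j(1−x_{j+1})`, exit `λ_n x_n`). Given `J` the
profile obeys a forward recursion from initiation that is numerically
stable on the high-density branch and a backward recursion from the exit
stable on the low-density branch; the true profile follows the forward
branch upstream of the shock and the backward branch downstream, and the
branches admit a handoff at position m iff `λ_m f_m (1−b_{m+1}) ≥ J`.
That predicate is monotone in `J`, so the flux is found by bisection
(vectorised across transcripts), the profile assembled piecewise at the
best handoff, and the result polished by Levenberg–Marquardt on the full
dynamics with the tridiagonal Jacobian. Chains whose multi-bottleneck
shock structure defeats the piecewise start (rare at the default
conditions) fall back to a trust-region root solve and, if needed, stiff
integration of the dynamics over increasing horizons. The solver refuses
to return a state whose dynamics residual exceeds 1e-8; the independent
oracle in the tests is long-horizon LSODA integration.

## Downstream statistics

* **Stalling**: per transcript, positions with normalized density
  strictly above `μ + 2σ`, population SD, both computed on that
  transcript's own profile — calls are invariant to rescaling, a uniform
  profile yields none.
* **CRI**: synonymous families from the standard genetic code (stops
  grouped); `S_j` restricted to codons present on the transcript,
  including j itself, as the per-transcript occurrence means require.
  Single-member families are identically 0; families with zero total
  density are undefined and excluded. Aggregation keeps transcripts with
  both ribosome and mRNA length-normalized abundance strictly above 10
  (configurable) and averages unweighted (abundance weights optional).
  Condition comparison: paired two-sided Wilcoxon signed-rank per codon
  over transcripts defined in both conditions, codons with <5 pairs
  flagged and skipped, all-zero difference vectors reported as NA, and
  Benjamini–Hochberg q-values added alongside the raw p-values (64
  parallel tests).
* **Evaluation**: abundance PCC/MSE on the count and per-million scales;
  per-isoform profile PCC against the true read placements for every
  transcript with any true reads (undefined PCCs — constant vectors —
  count against the >0.9 fraction and are excluded from the mean);
  stalling sensitivity/precision pooled over transcripts, with truth
  annotated by the same `μ + 2σ` rule on the true normalized profiles.
  The uniform baseline (every read split `1/|M|`, no iteration) is the
  comparator a naive pipeline would produce.

## Problem sizes

The validation suite and the acceptance script run the pipeline at desk
scale: 300 genes (~590 isoforms, ~440 of them expressed), 2×10^5 reads,
200 abundance-only iterations, and 10 joint-loop iterations warm-started
from the abundance-only fixed point with a refit every iteration at
`samples_per_bin = 2000` — the warm-started loop's metrics plateau after
roughly five iterations, consistent with warm-start convergence being
fast. End to end this is about ten minutes on one CPU core.

## Limitations

* The simulator omits sequencing errors, rRNA/tRNA contamination,
  nuclease sequence bias, UTRs and length-variable footprints; passing
  recovery tests here demonstrates the allocation machinery under known
  truth, not robustness to real library artefacts.
* The shape model sees only codon identity in a fixed window; it cannot
  represent RNA structure, nascent-peptide effects, or
  transcript-position trends, and at desk-scale training sizes its
  predictions are substantially shrunk toward the mean — it improves
  allocation where candidates differ in sequence context, it does not
  reproduce absolute dwell magnitudes.
* Genome-space (spliced) alignment is out of scope; alignments must be in
  transcript coordinates.
* CRI compares codons within transcripts and is robust to per-transcript
  scaling, but systematic P-site offset errors shift all codon
  attributions coherently and will distort it.
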