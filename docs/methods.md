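# Methods

## Model

`triframe` classifies DNA reads into protein domain families without
aligning or error-correcting them. The working assumption is that a domain
family is recognizable from short conserved peptide motifs, and that even
when insertions/deletions scramble the global reading frame, every local
stretch of a read is in *some* frame — so a representation that keeps all
three forward-frame translations side by side preserves the motif signal.

**Encoding.** A read of length *L* is translated in frames 0, 1, 2 (frame
*j* yields ⌊(L−j)/3⌋ residues). Translation does not stop at stop codons:
reads are fragments and frameshifts make internal stops ordinary, so stops
(and untranslatable codons, e.g. containing N) map to a 21st symbol `*`.
Each frame's one-hot matrix becomes one channel of a `3 × window × 21`
tensor; rows beyond the translation are all-zero padding. The reverse
complement is encoded separately, covering all six frames. The window is
1000 codons (3,000 nt) at full scale; longer reads are cropped into
consecutive 3,000-nt fragments and each fragment is scored separately.

**Network.** One fixed-size convolutional layer (default 128 filters of
size 3 — codon-scale pattern detectors) merges the three channels: each
filter is three `h × 21` matrices whose window dot-products are summed
before the ReLU. A second layer applies filters of sizes
[8, 12, 16, 20, 24, 28, 32, 36], 256 each (2,048 total — accuracy saturates
beyond that), to the first layer's feature map. Max-over-time pooling keeps
each filter's largest activation, making the feature vector independent of
input length; dropout 0.5 follows pooling, then a 512-unit hidden layer and
a softmax output. The first-layer size/count, hidden width and dropout rate
are package choices; the second-layer size grid and total filter count
follow the saturation analysis above. Ablation variants are configurable:
a nucleotide-level `L × 4` encoding with filter sizes tripled (same genomic
extent), a three-branch variant that processes each frame channel with the
matching slice **w**ⱼ of the first-layer filter and shares all deeper
parameters across branches, a single-layer variant, and an extra 64×size-3
third layer.

**Padding neutrality.** Window positions that overlap zero-padding are
masked out of every layer and out of the max-pool. Without masking, learned
biases would give all-zero windows a nonzero activation and padded inputs
would score differently; with it, padding invariance is exact and is tested
as such.

**Desk scale.** The numpy implementation (im2col + BLAS matmul, analytic
gradients, Adam) trains the desk configuration — window 128 codons, 32
size-3 filters, second-layer sizes [4, 8, 12] × 24 filters, 64 hidden units,
~10⁵ parameters — in seconds per epoch on one CPU. Gradients are verified
against central finite differences for every variant (relative error
< 10⁻⁴).

## Training and rejection

Training minimizes mini-batch cross-entropy (Adam, lr 10⁻³, batch 64 —
community defaults; the optimizer is not dictated by the method). With
Outlier Exposure, each in-distribution batch is paired with an equal-size
outlier batch drawn with replacement, adding λ·KL(U‖Q) with λ = 0.5 to the
objective, where Q is the model's predictive distribution on the outlier
and U is uniform. λ = 0 recovers plain cross-entropy exactly. Probabilities
are clamped to [10⁻¹², 1] inside both losses; the induced bias is far below
measurement noise. Training reads are plus-strand only — strand handling is
inference's job via the six-frame scheme.

Rejection thresholds the max-softmax score. Calibration sweeps candidate
thresholds (midpoints between consecutive distinct observed scores, plus
sentinels 0 and 1, so tie ordering is irrelevant) and keeps the F1-maximal
threshold, tie-broken to the smallest. Recall counts accepted-and-correct
in-distribution reads over all in-distribution reads; precision counts
in-distribution reads among all accepted reads; when nothing is accepted,
precision is defined as 1 so the sweep is total. A read longer than the
window is rejected or accepted *per read*, after aggregating over fragments
and strands by the largest maximum softmax — the alternative (per-fragment
rejection) would be stricter for long reads and is not implemented.

## Synthetic data generator

The generator replaces a large curated reference set (real pipelines use
thousands of homologous coding sequences per label) with families whose
*only* reliable family signal is a planted conserved motif:

- One random 120-residue background protein is shared by all families
  (configurable off); each family plants one 12-residue motif, distinct
  across families, at a random interior position (margin 20 residues from
  the termini). Sharing the background makes the motif the discriminative
  signal — matching how the method is interpreted (filters should recover
  motifs) — rather than letting families be distinguishable everywhere.
- 24 members per family copy the consensus inside motifs and substitute
  non-motif residues i.i.d. at rate 0.10 (uniform over the 19 alternatives).
  Members are split 80/20 into train/test references *before* read
  simulation, so no coding sequence contributes reads to both sides.
- Members are reverse-translated with uniformly random synonymous codons,
  so frame-1/2 translations differ between references while the in-frame
  motif peptide is invariant — the nuisance structure the classifier must
  see through.
- Reads: fixed 300-nt reads from the 360-nt references with uniform start
  positions (so every frame offset occurs in every channel across the
  training set, and the interior margin guarantees every read covers the
  motif), plus-strand by default, at configurable fold coverage. Errors are
  i.i.d. per base at the configured rate with type mix
  substitution:insertion:deletion = 10:60:30 (a standard long-read
  simulator's CLR default); substitutions are uniform over the other three
  bases, insertions add one uniform base. Determinism: every read's RNG is
  keyed by (seed, reference index, read index), independent of iteration
  order.
- Outliers: either uniform random DNA or (default) reads from decoy
  families generated with an independent seed and verified motif-disjoint
  by exact substring absence. Decoys are the default because realistic
  out-of-distribution reads are biological-like sequence, not noise.

What the generator deliberately does **not** emulate: homopolymer-biased or
quality-dependent errors, chimeras, instrument length distributions, codon
usage bias, and realistic protein composition. Passing tests therefore show
that the *method's mechanisms* work (frame-tolerant motif detection,
error-augmentation benefit, OE-sharpened rejection), not that any
particular accuracy carries over to real instruments or real families.

## Desk-scale experiments (benchmarks module)

Problem sizes were set so each experiment runs in minutes on one CPU:

- **Sanity fit**: 3 families, error-free reads at 9× coverage (~200 reads
  per family), 10 epochs. Expected: ≥99% training accuracy, ≥95% holdout
  (10% read holdout) accuracy.
- **Error augmentation**: 5 families; a model trained on {0%, 10%}-error
  reads vs one trained on 0% only, both 12 epochs, judged on 10%-error
  reads from held-out references, 3 seeds.
- **Outlier Exposure**: same data plus 500 decoy-family training outliers;
  calibration on a holdout mixture; detection F1 measured on a disjoint
  ~10%-in-distribution mixture whose outliers come from decoy families
  generated with a different seed than the training outliers; 3 seeds.
- **Frame-order probe**: all six permutations of the three frame channels
  fed to a fixed trained model. Order-insensitivity is an emergent property
  that strengthens with training coverage, so this probe trains at the
  highest desk-affordable coverage rather than the sanity coverage.
- **Motif recovery**: second-layer filters ranked by how often each wins
  the max-over-time pool (top-1 per read); for the top filter, the
  receptive-field peptide window (first-layer span + filter size − 1
  residues) under the winning position is emitted per frame channel.
  Windows from each read's protein-frame channel are stacked and their
  per-column majority consensus is compared to the planted motif
  (contiguous match of ≥ 5 residues, majority of families). This probe also
  uses the well-trained (high-coverage) model: interpretation of an
  underfit model reflects its shortcuts, not the motifs.

## Numerical and design notes

- Candidate thresholds at calibration are midpoints, not observed scores;
  F1 is compared exactly against a brute-force sweep in tests.
- The six-frame aggregation uses argmax of max-softmax over
  (fragment × strand) passes; strand symmetry of the result is exact and
  tested to 10⁻⁹.
- Reads shorter than the network's receptive field (fixed-layer span +
  largest second-layer filter) get a distinguished `too_short` status
  instead of a score.
- Model files are a versioned `.npz` with the architecture embedded as
  JSON; loading reproduces bit-identical predictions.
- Fragment extraction can emit either pool winners only (default) or every
  positively-activated filter's windows (`pool_winners_only=False`), since
  "most frequently activated" admits both readings.

## Known limitations

- Frame-order insensitivity at desk scale is noisy: the spread over the six
  channel orders decreases with coverage (reproducing the qualitative
  trend) but does not reliably reach the near-zero spread seen with
  hundreds of thousands of training reads; see the acceptance output's
  `frame_order_accuracy_spread`.
- The classifier cannot localize domain boundaries within a read; calls are
  per read (or per 3,000-nt fragment internally).
- The i.i.d. error model understates bursty indels; the augmentation
  benefit measured here may differ on instrument-realistic error profiles.
- Training determinism is guaranteed for a fixed BLAS/thread configuration;
  across different BLAS builds, bit-identical trajectories are not.
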