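# Methods

## The model

`fpgan` generates new compound ideas as molecular *fingerprints* rather
than SMILES strings or graphs.  A molecule is encoded as a fixed-length
binary key vector — MACCS structural keys stored in a 168-position vector
(the native dictionary emits 167 keys; the remaining positions are
constant-zero padding so every tensor in the models has the same length) —
and a generative adversarial network is trained to produce new key vectors
that resemble a reference library.  Because a fingerprint cannot be
decoded back into a structure directly, generation is always followed by a
Tanimoto similarity search of a real compound library: the generated
vectors act as queries, and the deliverable is the set of retrievable,
purchasable molecules most similar to them.

Three workflows build on this core:

* **druglike** — an unconditional deep-convolutional GAN (dcGAN) trained
  on a single class of "real" fingerprints; sampling gives drug-like
  queries.
* **target_biased** — a conditional GAN (cdcGAN): a one-hot class label
  (active/inactive against a target) is appended to both the generator's
  noise vector and the discriminator's input, so sampling with the active
  label steers generation toward the active class.
* **compound_series** — the conditional GAN plus a *mask layer* appended
  to the generator output: given a maximum common substructure (MCS)
  shared by a compound series, the layer computes
  `y = x * unmask + mask`, where `mask` is 1 at the MCS's fingerprint
  feature bits and `unmask = 1 - mask`.  Masked positions are exactly 1 in
  every sample, so every query provably carries the core's feature bits.
  Retrieved hits are then confirmed in two rounds: a cheap containment
  screen on a 1024-bit path fingerprint (linear fragments of 1–7 bonds,
  folded) followed by exact subgraph isomorphism, which is the
  authoritative check.

### Networks

The discriminator is one of six named deep-convolutional classifier
variants (LeNet-5, AlexNet, ZFNet, VGGNet-11/13/16).  All share one
contract: a dense input projection over the fingerprint bits (plus the
condition one-hot when conditioning), a reshape to a single-channel 1-D
signal, convolution/pooling stacks per the variant, and a 2-class softmax
head — so any variant can serve as the GAN discriminator interchangeably.
The canonical image architectures are translated to 1-D: 2-D kernels
become 1-D kernels of the same extent, and channel widths are scaled down
(about 1/8 of the image-scale widths) to match a length-168 binary signal;
the full layer table ships as versioned package data
(`fpgan/data/architectures.yaml`).  VGGNet-11/13 are obtained from
VGGNet-16 by dropping the tagged block-internal convolution layers, which
reproduces the canonical 8/10/13 convolution-layer counts and makes the
parameter counts strictly ordered.

The generator reverses the convolution process: a 100-dimensional standard
normal noise vector (plus condition one-hot) is densely projected to a
coarse 16-channel signal of length 21 and refined through four
convolutional layers (16, 8, 4, 1 channels; nearest-neighbour ×2
upsampling before the middle ones; batch normalization and leaky-ReLU
after all but the last) to a length-168 sigmoid output, so every position
lies in [0, 1] and the mask layer's fixed point at 1 is exact.
Fingerprints are obtained by thresholding at 0.5 (the threshold is a
sampling-time parameter; raising it can only clear bits).

The networks are implemented in a small seeded NumPy layer library
(`fpgan.nn`): float32 throughout, convolution evaluated as im2col plus
GEMM with the input gradient as a correlation with the flipped kernel, and
an Adam optimizer with an optional L2 penalty on kernel matrices
(default coefficient 1e-4; the protocol names the penalty but not its
size).  Gradient correctness is verified against finite differences in the
test suite, and all randomness flows through explicit
`numpy.random.Generator` seeds, so training runs are bit-reproducible and
the alternation contract can be audited by checksumming parameters.

### Training protocol

Discriminator pre-training: stratified 10-fold cross-validation on a
labeled active/decoy fingerprint set, 100 epochs per fold by default,
2-class cross-entropy, Adam.  The published adversarial-stage learning
rates (1e-6 discriminator / 1e-3 generator) are kept as the
`TrainingConfig` defaults, but pre-training uses the optimizer-default
1e-3 (`pretrain_learning_rate`): the protocol states no pre-training rate,
and at 1e-6 a freshly initialized network barely moves within 100 epochs.

Adversarial training alternates two phases per mini-batch (batch size 32,
one full pass over the real set per epoch, 800 epochs by default): the
discriminator updates on a real batch labeled positive and a freshly
generated batch labeled negative while the generator is frozen; then the
generator updates through the frozen discriminator with positive labels on
its own samples (the non-saturating form of the minimax objective).
"Frozen" is structural — each phase steps only its own optimizer — and the
test suite verifies it by parameter checksums.  The conditional loop is
identical except that real batches carry their class labels and generated
batches draw labels from the empirical label distribution.

For desk-scale runs the package provides `TrainingConfig.demo_scale`:
200 adversarial epochs on 2,000 real fingerprints, discriminator rate
1e-4.  The published 1e-6 presumes a pre-trained discriminator; training
one from scratch at that rate within a few hundred epochs is not possible,
so the scaled protocol uses an ordinary Adam-scale rate while preserving
the generator-faster-than-discriminator ordering.

## Synthetic study conditions

No external database is required; two generators define the study
conditions and are first-class, tested code.

* `make_synthetic_fpset` draws Bernoulli fingerprints with 20 planted
  *signature bits*: actives carry each signature bit with probability 0.9,
  inactives with 0.1, and all other bits are Bernoulli(0.3) in both
  classes (defaults: 2,000 per class, length 168).  This emulates the
  marginal class structure of a real active/decoy fingerprint set — a
  depth-1 stump on one signature bit already achieves the closed-form
  accuracy 0.9, and the Bayes AUC is effectively 1 — but it deliberately
  has independent bits.  Real MACCS keys are strongly correlated
  (substructures imply one another), so passing tests on this fixture
  demonstrates that the models learn marginal bit structure and class
  conditioning, not that they capture key-key correlations in real
  libraries.  A two-signature variant gives each class its own opposing
  20-bit block and is used to probe conditioning.
* `make_synthetic_library` builds a toy SMILES library by decorating
  scaffolds with 1–3 small substituents; a configurable fraction start
  from a planted core (default: pyrazole carboxamide,
  `O=C(N)c1cc[nH]n1`) and the rest from six core-free ring systems.
  Ground-truth core containment is recorded by an exact subgraph match at
  build time.  Substituents attach only at carbon positions: substituting
  an N–H would alter hydrogen-count-dependent structural keys of the core
  itself, and the fixture is designed so key-based screening of the core
  has no false negatives.  The molecules are small and synthetically
  naive; the library exercises search and confirmation logic, not
  chemical realism.
* The decoy-matching fixtures draw logP correlated with MW (logP ≈
  MW/100 + noise), as in real compound collections.  This matters: after
  joint z-scoring both properties have unit variance, so with
  *uncorrelated* toy properties the first principal component is
  degenerate and the 1-D reduction cannot prefer the mismatched axis.

## Numerical and design choices

* **Decoy matching** z-scores MW and logP jointly over actives+pool, fits
  a 1-component PCA on the *combined* standardized set (fitting on the
  actives alone can collapse onto a direction orthogonal to the
  active/pool mismatch), estimates the active-score density with a
  Gaussian KDE (Scott bandwidth), and samples the pool without replacement
  with probability proportional to that density.
* **Tanimoto of two all-zero vectors is 0**, so an empty generated
  fingerprint never ranks as a perfect hit.
* **Search bands**: a library molecule's score is its maximum Tanimoto
  over all queries; its band is the highest configured threshold it
  clears, and band counts are cumulative (non-increasing in the
  threshold).  Candidate ranking sorts by (similarity, QED)
  lexicographically, with molecule id as the deterministic tie-break.
* **Generation metrics**: uniqueness = distinct bit-vectors / sample
  size; novelty = unique vectors absent from training / unique vectors;
  diversity = 1 − mean pairwise Tanimoto; similarity = mean Tanimoto over
  the generated × training cross product.  Pairwise means are exhaustive
  up to 2×10⁶ pairs and seeded-subsampled beyond (flagged in the report).
  Every generated bit-vector counts as "valid" in the uniqueness
  denominator — validity is a SMILES-level concept that does not apply to
  fingerprints.
* **AUC** uses the Mann–Whitney rank formulation with tie midranks;
  confusion counts threshold the positive-class probability at 0.5, and
  accuracy/precision/recall/F1 are derived from those counts.
* **Degenerate inputs** fail loudly: zero-variance property columns,
  single-class label vectors, empty fingerprint sets, unparsable SMILES
  (collected and counted when scanning libraries, raised when encoding a
  single molecule), non-finite training losses (abort with epoch and
  phase).

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the package's own study conditions: discriminator
cross-validation on 4,000 fingerprints with 2 folds evaluated at 12 epochs
(all six architectures at 1 fold × 4 epochs); adversarial training for
200 epochs on 2,000 actives across 3 seeds; conditional training for 120
epochs on 1,000 per class; 10,000 masked samples per seed; a
5,000-molecule search library with 100 queries; 100 repeated decoy draws
from a 1,000-molecule pool.  The default configuration (800 epochs,
10 folds × 100 epochs, 10,000 samples) reproduces the full published
protocol and runs unchanged — only longer.

## Known limitations

* Fingerprints are not invertible; the pipeline's output is always a set
  of retrieved library molecules, never de-novo structures.  Everything
  downstream of retrieval (docking, free-energy scoring, assays) is out of
  scope.
* The mask guarantee is a statement about fingerprint bits, not
  molecules: a retrieved molecule matching a masked query still requires
  subgraph confirmation, because distinct substructures can share key
  bits and folded path fingerprints can collide.
* The synthetic fingerprint distribution has independent bits; results on
  it say nothing about a model's ability to reproduce key-key
  correlations of real libraries.
* The scaled-down adversarial runs use a discriminator learning rate of
  1e-4 (see above); with the published 1e-6 and a pre-trained
  discriminator the dynamics may differ.
* Exact SMARTS of the published compound-series cores are not
  machine-readable from the source; the default core here is a
  representative pyrazole carboxamide and is configurable.
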