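# Methods

This note records the model behind the package, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and
do not show.  Every number quoted here is computed by the test suite,
the examples or `scripts/acceptance.py`; nothing is asserted that the
code does not measure.

## The layered model

A `LayeredModel` is an ordered list of layers of five kinds —
convolution (single 2-D filter, valid padding, configurable stride),
adaptive average pooling to a fixed `g × g` grid, dense, elementwise
activation, and a softmax output layer carrying an ordered class-label
tuple.  Hidden layers compute `P_i = a(X_i · Y_i) + B_i`; the output
layer applies softmax to the logits `X · Y + B` and predicts the
argmax label, ties to the lowest class index, so every pass is fully
deterministic.  The representation is deliberately framework-free:
the integrity protocol, not the backbone, is what the package studies,
and a four-layer toy network exercises every code path the protocol
has (parameterized layers, parameter-free layers, structural metadata,
class labels).

Adaptive pooling was chosen over fixed-window pooling for one specific
reason: the severe attack edits the first convolution's stride, and a
fixed output grid lets that edit change the numbers flowing downstream
without breaking shape compatibility — the same behaviour global
average pooling gives real backbones.  When a structural edit *does*
break shape composition, the forward pass raises naming the offending
layer, and impact evaluation counts every probe as misclassified.

## Canonical serialization and the hash chain

Hashing tensors requires a canonical byte encoding.  A layer
serializes as: fixed-field structural record (layer id, kind code,
activation code, stride, filter size, output size), name and class
labels (length-prefixed UTF-8), then weights and bias as row-major
little-endian IEEE-754 float64 with explicit shapes.  Non-finite
parameters are rejected.  Serialization and deserialization are
bit-exact inverses (property-tested), which is what makes restoration
bit-exact end to end.

The chain is `h_i = H_k(h_{i-1} ‖ delta_i)` with a fixed all-zero
32-byte genesis.  `delta_i` is an elementwise subtraction of weights,
bias and structural integers when consecutive layers have aligned
shapes (labels of both layers appended verbatim, since labels are not
numeric), and otherwise the concatenation of both full serializations
— a shape change must perturb the hash.  At the first layer the delta
is the layer's own serialization.  The chain key is derived from the
wrap seed and stored in the central ledger block, mirroring the
protocol's placement of hash keys in the central store; the package
does not claim security against an adversary holding both the model
and the ledger (see Limitations).

### Tamper localization

A naive audit that recomputes the chain against the live model flags
layer `i+1` whenever layer `i` changes, because `delta_{i+1}` involves
`params_i`.  Since the audit must name exactly the edited layers (the
detection benchmark requires zero false positives on untouched
layers), validation separates two concerns:

1. **Model vs ledger** — each layer's live serialization is compared
   with the decrypted parameter copy in its ledger block; a mismatch
   flags that layer and only that layer.
2. **Ledger integrity** — the chain is recomputed over the ledger's
   own parameter copies and compared with the stored hashes, and each
   chain record's signature is verified under the layer's public key;
   disagreements flag the earliest offending record (reasons: hash,
   signature, or missing record).

Blame therefore always lands on the earliest layer exhibiting a cause,
and downstream layers are never implicated by upstream edits.

### Restoration

Restoration decrypts the stored parameters of every flagged layer
(falling back to the predecessor block's encrypted copy of its
successor), writes them back, and re-validates, looping up to
`max_iterations` (default 3 — the protocol's "continue until valid
again" needs a termination bound).  If no intact encrypted copy of a
flagged layer survives, restoration raises an unrecoverable-tamper
error rather than guessing.  Because the ledger stores canonical
serializations, restoration recovers weights, biases, structural
fields and class labels bit-exactly; the acceptance benchmark checks
bit-identical forward outputs on a 50-image probe for all three attack
severities.

## Cipher suites

The suite interface bundles public-key encryption, a keyed digest,
and sign/verify.  Two implementations ship:

- **default** — per-layer RSA key pairs (512-bit modulus from two
  256-bit Miller–Rabin primes, e = 65537), hybrid encryption (RSA-
  wrapped 256-bit session key, SHA-256 counter-mode keystream,
  HMAC-SHA256 authentication tag), HMAC-SHA256 keyed digests, RSA
  signatures over SHA-256 digests.  The session key is derived
  deterministically from (public key, plaintext) so that wrapping a
  model twice with one seed produces byte-identical ledgers; the cost
  is that equal plaintexts yield equal ciphertexts, acceptable for a
  reproducibility-first research artifact.  Key sizes are
  demonstration grade: the package studies the protocol, not key
  hardness.
- **des** — a complete from-scratch DES (verified against two
  published known-answer vectors), used in CBC mode with PKCS#7
  padding and a CBC-MAC tag for encryption, and as a CBC-MAC for the
  keyed digest and signatures.  DES is a symmetric cipher, so this
  suite's "public" and "private" keys are role-tagged views of one
  shared 8-byte secret; it exists because the protocol names DES as
  its primitive, while the default suite provides the genuinely
  asymmetric semantics the protocol's key-pair language implies.

Wrap-time key pairs are fixed for the model's lifetime (regeneration
per pass would add nothing observable in this setting and would break
ledger reproducibility).

## The attack simulator

- **Type 0 (mild)** — permute the output layer's class labels;
  default permutation is a reversal (deterministic), a seeded random
  permutation is available.  No numeric parameter moves.
- **Type 1 (average)** — seeded Gaussian noise (mean 0, σ default
  0.1) on the weights of every fully-connected layer, hidden dense
  layers and the output projection alike; biases are untouched.
- **Type 2 (severe)** — noise on every parameterized layer's weights,
  plus structural edits: first convolution stride +1 and a class-label
  permutation.

Attacks act on a copy and return a report (layers touched, parameter
count changed, permutation, seed); identical specs and seeds produce
byte-identical attacked models.

## Synthetic fixtures and what they show

The image generator emits four separable classes (one per quadrant,
with class-specific blob count and intensity over pixel noise) in the
class-per-folder layout of public MRI collections, at 64×64 and ~tens
of images per class.  These are statistical stand-ins with no
radiological realism: passing benchmarks on them demonstrates the
*protocol* (detection, localization, restoration, ordering of attack
severities) and the *selection machinery*, not clinical performance.
Dataset-scale accuracy tables from real MRI data are explicitly out of
scope.

Toy backbones mirror the full-scale trio's named feature layers
("avg pool", "global avg pool", "fc") at widths (32, 16, 16); a
`full_widths` switch emits the full 2048/1000/1000 widths solely to
check the fused dimensionality claim (2048 + 1000 + 1000 = 4048).
Because training is out of scope, the toy output layer is *calibrated*
in closed form: its weights become the class-centroid matrix of the
penultimate feature space and its bias `−‖c‖²/2`, making the softmax
argmax a nearest-centroid rule.  This yields a genuinely accurate
clean classifier (probe accuracy 1.0 on the separable fixture), which
the severity-ordering benchmark needs as its reference point.

The planted-feature table plants `n_informative` columns among pure
N(0, 1) noise.  Each planted column carries class means equally spaced
over a span of `effect_size` noise standard deviations, in a
per-column random class order (adjacent classes `effect/(K−1)` σ
apart).  The span definition — rather than, say, drawing class means
with standard deviation `effect` — keeps every single feature weakly
informative, so cross-validated accuracy keeps rising as more planted
columns enter a subset instead of saturating at a handful.  A recovery
benchmark is only meaningful if the fitness landscape actually slopes
toward full recovery; under this design the ground-truth mask is
strictly fitter than random masks of equal size (paired over seeds),
and the GA's best mask recovers a median 95% of the planted columns
under the benchmark conditions (200 features, 20 informative, effect
2.0, population 30, 50 generations, 200 samples, 4 classes).

## Feature pipeline choices

- **Mode ordering** — continuous features are rounded to `decimals`
  (default 2) before the mode is taken; within a column, count ties
  resolve to the smallest qualifying value, and between columns, mode
  ties keep the original index order, making the permutation a
  deterministic bijection.  Ordering is a pure permutation; no values
  change.
- **Entropy gate** — the fitness entropy is computed on the pooled
  values of the selected columns, quantile-binned into 10 bins, with
  the Laplace constant λ (default 1) added to bin counts before
  normalization.  Natural logarithms throughout, so the 10-bin
  entropy is at most ln 10 ≈ 2.303; the default threshold τ = 2.5
  leaves the gate open unless a user tightens it (τ is a cap on
  admissible disorder, and a per-feature variant of the gate was
  considered and rejected as the pooled-histogram reading matches the
  "proportion of samples" framing).  λ also scales the Gaussian NB
  variance floor.
- **Fitness** — gated chromosomes score 0; others score mean
  stratified 3-fold Gaussian NB accuracy on the masked columns.
  Fitness values are cached by mask, so elitist re-evaluations are
  free.
- **GA mechanics** — per-bit initialization at 0.5; roulette-wheel
  parent selection with a uniform fallback when every fitness is 0;
  uniform crossover at rate 0.8; per-bit mutation at rate 0.001; the
  top B = 6 parents survive unconditionally and the rest of the next
  population is the fittest of remaining parents and offspring, so the
  best fitness is non-decreasing (tested).  Termination at
  `max_iterations` or 50 stagnant generations.  If the final
  population is entirely gated, the least-disordered chromosome is
  returned with an explicit warning flag.  The selector never forces
  an output cardinality; selected-set sizes are data-dependent.
- **Classification** — built-ins are Gaussian NB and a
  nearest-centroid linear discriminant behind a pluggable registry;
  metrics are macro-averaged over a stratified 70–30 split.  Rows are
  put into a canonical content-digest order before splitting, so the
  metrics depend only on the data, not on row storage order.
- **Leakage** — mode ordering is a label-free permutation, so
  computing it on the whole table leaks nothing into the split; the
  fitness's cross-validation happens inside the GA and is reported as
  fitness, never as final metrics.

## Benchmark problem sizes

The standard experiments (in `securecnn.benchmarks`, driven by
`scripts/acceptance.py`) use: a 5-layer toy model and 100 perturbation
trials for detection sensitivity (magnitudes log-uniform from one ulp
to 1.0, slots uniform over every weight and bias); 50 probe images for
restoration bit-exactness; 10 seeds × 48 probe images for severity
ordering; 5 seeds of the planted benchmark for GA recovery; and 100
random models for wrapping transparency.  These sizes keep the whole
suite and the acceptance script inside about a minute each on one CPU
while leaving every measured rate at its ceiling or floor rather than
in a noisy middle.

## Known limitations

- No protection against an adversary who controls model and ledger
  stores simultaneously — they could rewrite both consistently; the
  private keys live in the layer blocks, as in the protocol this
  package implements.  There is no consensus, mining, or multi-party
  replication; the "cloud" copy is an availability mechanism behind a
  pluggable store interface.
- The cryptographic primitives are demonstration grade (textbook RSA
  at small modulus, deterministic hybrid encryption, single DES) and
  must not be reused as security components elsewhere.
- The toy networks are single-channel and small; adapters for real
  deep-learning frameworks are intentionally out of scope.
- Synthetic separability means accuracy ceilings are easy to reach;
  severity-ordering results show directions and protections, not
  magnitudes transferable to real datasets.
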