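# Methods

## Model and learning procedure

`dbnlab` trains stacks of binary restricted Boltzmann machines. One RBM has
visible units v ∈ {0,1}^m (gray-level pixels in [0,1] are accepted as
clamped probabilities), hidden units h ∈ {0,1}^n, weights W (m × n) and
optional bias vectors. The joint energy is E(v,h) = −vᵀWh − b_vis·v −
b_hid·h, and p(v,h) ∝ e^(−E). Learning is CD-k: the positive phase clamps
the visibles and computes hidden probabilities H_D = sigm(V_D W + b_hid);
the negative phase binarizes the hiddens and alternates block Gibbs steps
(reconstruct visibles, recompute hiddens) k times; the update is

  ΔW = η (V_Dᵀ H_D − V_Mᵀ H_M) / S,  Δb_vis = η·mean(V_D − V_M),
  Δb_hid = η·mean(H_D − H_M),

averaged over a mini-batch of S patterns. A deep belief network is trained
greedily, each layer on the deterministic probability propagation of the
stack below; training layer ℓ never modifies layers < ℓ.

Sampling policy (all modes implemented, defaults first): hidden states are
binarized when they drive a reconstruction, but the correlation products use
the real-valued probabilities, and the reconstruction V_M is mean-field —
the standard low-variance CD recipe. `sample_visible=True` samples binary
visibles in the chain; `strict_binary=True` binarizes every intermediate
state including H_D, which makes the chain a literal stochastic trace and is
what the step-through oracle test checks against. Inter-layer inputs are
probabilities by default; a sampling propagation mode exists but is not used
for training.

Biases are on by default and updated as above; with `use_biases=False` both
bias vectors are identically zero throughout, matching the weights-only form
of the update rule. Momentum (default 0) and L2 weight decay (default 0)
are applied when an update is added to the weights, not inside the update
itself, because decay needs the current W; with both at zero the applied
step is exactly the printed CD rule.

## Data-parallel semantics

Each mini-batch is split into contiguous data-packets of `packet_size`
patterns (default 125, the per-worker share in the cluster setting this
emulates; a ragged final packet is allowed). One simulated worker computes
CD-k plus the update on its packet; the master averages updates weighted by
packet size and applies the result before the next mini-batch (synchronous;
no stale-gradient mode). Workers are simulated by sequential execution —
the contract is semantic, not a transport: (i) every packet's randomness is
a pure function of (seed, layer, epoch, batch, packet), so results are
independent of execution order and bit-reproducible; (ii) because the update
is linear in the per-pattern average, the weighted average of packet updates
equals the serial mini-batch update exactly (tested at ≤ 1e−10 in double
precision, observed ~1e−16). A fresh seeded permutation is drawn every
epoch.

Because the workers actually run one after another, wall time is nearly flat
in S. The benchmark therefore records two times per cell: the sequential
wall time (reported, never asserted — it is a hardware measurement) and the
*simulated parallel execution time*, defined as the per-update critical path
(the slowest packet's compute time) plus the master's coordination time
(splitting, averaging, applying). The simulated time is what a k-worker
cluster would spend and is the quantity whose decrease with S the trade-off
tests assert. The overhead fraction — coordination share of simulated time —
rises with S (more packets to average per update, less compute per update on
the critical path), mirroring the communication overhead of a real cluster.

## Parameters that matter

- η (learning rate), default 0.1: standard for [0,1] data with σ=0.01
  Gaussian weight initialization; large enough to learn bars-and-stripes in
  a few hundred epochs, small enough not to oscillate.
- k (CD chain length), default 1: CD-1 is the usual pretraining choice; the
  enumeration tests quantify how the update's alignment with the true
  log-likelihood gradient improves from k=1 to k=25.
- S (`minibatch_size`), default 125, and `packet_size`, default 125: S is
  the experimental variable of the benchmark; S = k_workers × packet_size.
- epochs: task-dependent; the benchmark uses 10 per layer (see below).
- precision: double by default; single precision changes the final
  bars-and-stripes reconstruction error by < 1e−3 (tested), consistent with
  single precision being safe for this model family.
- Weight init: i.i.d. N(0, 0.01²), biases zero, seeded.

Seeding discipline: one master seed; every consumer (weight init, epoch
permutations, each packet's Gibbs chain, splits, generators) uses a
`SeedSequence` child keyed by integers identifying its position. Identical
seed + config ⇒ bit-identical trained weights.

## Synthetic data: what it emulates and what it does not

- `gen_bars_stripes`: the classic enumerable test distribution (every row
  constant or every column constant); exhaustive mode yields
  2^rows + 2^cols − 2 unique patterns. Small enough that the exact
  log-likelihood gradient and partition function can be enumerated
  (≤ 16 total units), which is what makes the CD-vs-exact oracle possible.
- `gen_prototype_digits`: one fixed random binary prototype per class plus
  i.i.d. pixel flips. It reproduces the *class structure* of a
  handwritten-digit benchmark at desk scale, not its geometry: within-class
  variability is unstructured noise, there are no strokes, translations or
  correlations between pixels. Passing the trade-off test therefore shows
  that representation quality degrades with mini-batch size on a task with
  real class structure — it does not certify error levels on natural images.
- `gen_dot_images`: N non-overlapping discs at random positions/radii,
  labeled by numerosity (the sample cognitive-modeling stimulus family);
  dot count is controlled, surface-area/density controls of the original
  stimulus sets are not reproduced.

All generators are pure functions of (parameters, seed).

## Benchmark configuration

The desk-scale task was fixed once: n = 4,000 prototype-digit images,
16 × 16 pixels, 10 classes, flip probability 0.4, architecture
[256, 64, 64, 128] (three RBMs, 28,672 weights — the reference stack's
shape at ~1/40 its size), CD-1, η = 0.1, 10 epochs per layer, packet size
25, grid S ∈ {25, 50, 100, 200, 400} (1–16 simulated workers), 5 replicate
networks per cell, readout evaluated on a held-out 1/6 split. The flip
probability is deliberately high: with light noise every representation —
trained or not — supports a near-0% linear readout and the quality trend is
unmeasurable; at 0.4 a linear readout makes enough errors that differences
in representation quality register in the metric. Problem sizes were chosen
so the full sweep runs in about a minute on one CPU core.

At these settings (seed 1) the sweep gives: readout error rising from
~14% (S=25) to ~31% (S=400), error-vs-log10(S) slope ≈ +14, simulated
parallel time falling monotonically with S (power exponent ≈ −0.6 to −0.7,
Spearman ρ = −1), overhead fraction rising from ~6% to ~40%. The
acceptance script recomputes all of these from scratch.

## Numerical choices

- `sigm` clips its argument at ±36 (float64) / ±16 (float32) before
  exponentiation. These are the tightest bounds at which the output still
  saturates past representable precision, so the function is overflow-free
  for any finite input *and* returns values strictly inside (0,1); values
  discarded by the clip are below one ulp of the result.
- `stoch` draws one uniform per element and compares `u < p`, so p = 0 and
  p = 1 are exact.
- Readout: the pseudo-inverse is computed by numpy's SVD-based `pinv` on
  [H | 1]; rank deficiency returns the minimum-norm solution with a
  warning. Classification ties break to the lowest class index. One-hot
  targets are 0/1.
- Fine-tuning uses plain seeded mini-batch gradient descent on softmax
  cross-entropy (the pretrained stack plus a zero-initialized head). This
  is a deliberate simplification — fine-tuning here is a quality probe, and
  first-order descent keeps the gradient finite-difference-checkable.
- Ragged packets/mini-batches: averaging is weighted by pattern count, so
  ragged blocks are exactly equivalent to the serial computation. A
  mini-batch larger than the dataset degrades to one full-dataset block
  with a warning.
- Degenerate inputs: epochs = 0 returns the initial parameters unchanged;
  η = 0 freezes weights; empty data, dimension mismatches, out-of-range
  probabilities and non-finite inputs raise with the offending quantity
  named.
- Trend fitters regress on log10; an exactly constant response is reported
  as slope 0 with r² = 1 (the flat line fits with zero residual, and the
  usual r estimate is undefined there).
- Model files are HDF5 with time-tracking disabled, so saving the same
  model twice is byte-identical; unknown format versions and truncated
  files raise clean errors.

## Limitations

- Binary/Bernoulli units only: no Gaussian-visible or softmax variants, no
  persistent CD, no deep Boltzmann machines, no top-down generative
  sampling from the stack.
- The simulated parallel time models compute critical path + coordination;
  it has no network-transport component, so its absolute values and its
  exponent are not hardware predictions — only the direction and rough
  shape of the trend are meaningful.
- The enumeration oracles are limited to ≤ 16 total units by design.
- The IDX reader loads files from disk (optionally gzipped); the library
  never downloads datasets.
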