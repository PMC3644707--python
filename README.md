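# dbnlab

Deep belief network pretraining with contrastive divergence, data-parallel
mini-batch semantics, and a time/quality benchmark harness.

## What this is for

Hierarchical generative models are a workhorse of computational cognitive
neuroscience: a stack of restricted Boltzmann machines (RBMs) learns, without
supervision, progressively more abstract distributed representations of
sensory data (vectorized images of handwritten digits, dot arrays for
numerosity perception, ...). Training such stacks is compute-hungry, and the
standard remedy is data-level parallelism: each mini-batch is split into
fixed-size *data-packets*, workers compute weight updates independently on
their packets, and a master node averages the proposed updates before the
next mini-batch. Growing the mini-batch lets more workers run at once — but
fewer, smoother updates also degrade the learned model. `dbnlab` implements
this whole stack as a tested library + CLI, including a simulated
master/worker loop whose averaging is provably equivalent to serial
mini-batch learning, and a benchmark harness that measures the
time-versus-quality trade-off as a function of mini-batch size.

## The model

An RBM is a two-layer stochastic network — visible units **v** (data) and
hidden units **h** (latent causes) joined by symmetric weights **W**, with no
intra-layer links — whose energy

    E(v, h) = −vᵀW h − b_vis·v − b_hid·h

defines a Boltzmann distribution over joint states. CD-k (contrastive
divergence) learning approximates the log-likelihood gradient by contrasting
data-clamped correlations with correlations after k steps of block Gibbs
sampling:

    ΔW = η ( ⟨v⁺h⁺⟩ − ⟨v⁻h⁻⟩ )

averaged over the patterns of a mini-batch of size S. A deep belief network
is built greedily: layer 1 models the raw data, each next layer models the
hidden activations of the stack below. Representation quality is probed by a
closed-form linear readout on the top-layer activations — one-hot targets T,
design matrix [H | 1], weights `pinv([H | 1]) · T` — scored as percent
misclassification on held-out data; an optional backpropagation pass
fine-tunes the whole stack with a softmax head.

The data-parallel semantics are exact, not approximate: because ΔW is linear
in the per-pattern average, the master's packet-size-weighted average of
worker updates equals the serial update on the concatenated mini-batch to
floating-point round-off (≤ 1e−10 in double precision). All randomness
derives from one master seed via per-(layer, epoch, batch, packet)
substreams, so results never depend on worker execution order.

## Worked example

```python
import numpy as np
from dbnlab import DeepBeliefNetwork, PseudoInverseReadout, gen_prototype_digits, substream

# 4,000 synthetic 16x16 "digits": 10 class prototypes + 40% pixel-flip noise
data = gen_prototype_digits(4000, n_classes=10, size=16, flip_prob=0.4,
                            rng=substream(0, (10,)))
train, test = slice(0, 3200), slice(3200, 4000)

dbn = DeepBeliefNetwork(hidden_layer_sizes=(64, 64, 128), epochs=10,
                        minibatch_size=100, packet_size=25, random_state=0)
dbn.fit(data.images[train])
print("connections:", dbn.count_parameters())

readout = PseudoInverseReadout().fit(dbn.transform(data.images[train]),
                                     data.labels[train])
print("held-out readout error: %.2f%%"
      % readout.error_pct(dbn.transform(data.images[test]), data.labels[test]))
```

prints

```
connections: 28672
held-out readout error: 11.50%
```

The stack has 256·64 + 64·64 + 64·128 = 28,672 connections; the readout
misclassifies 11.5 % of the held-out noisy images — far below the 90 %
chance level of a 10-class task at this noise. Estimators follow
scikit-learn conventions and compose with `Pipeline` and model selection;
the same operations are available as plain functions (`train_dbn_greedy`,
`fit_readout_pinv`, `packet_gradients`, `average_updates`, ...).

The CLI drives the same machinery:

```
dbnlab synth --kind protodigits --n 4000 --size 16 --seed 1 --out data.h5
dbnlab train --arch 256,64,64,128 --cd-k 1 --eta 0.1 --epochs 10 \
             --minibatch 100 --seed 1 --data data.h5 --out model.h5
dbnlab evaluate --model model.h5 --probe readout --data data.h5 --seed 1
dbnlab bench --grid 25,50,100,200,400 --replicates 5 --seed 1 --out bench.csv
```

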