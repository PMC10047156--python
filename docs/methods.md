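# Methods

## The channel model

A single-hidden-layer tanh classifier is treated as a two-stage discrete
channel: input class variable `Xin` → hidden layer `Y` → predicted class
`Xout` (argmax over tanh output activations, ties to the lowest index).
`Xin` is the *label* distribution, not the raw feature distribution: the
channel question is how class identity, not pixel identity, traverses the
network. Since every forward path passes through the hidden layer, all
input–output information is carried by `Y`; for a deterministic network
whose prediction is a function of the coarse-grained hidden state, the
triplet co-information `I(Xin;Xout;Y)` equals `I(Xin;Xout)` exactly (this is
asserted in the tests on fixture networks built to have that property; for
trained networks the argmax can depend on sub-threshold analog detail that
binarization discards, and the identity holds only approximately).

## Relay information

For a disjoint split `Y = Y_R ⊗ Y_0`, the relay information is the
co-information of `(Xin, Xout, Y_R)` with every entropy term conditioned on
`Y_0` (`H(·|Y_0) = H(·,Y_0) − H(Y_0)`). Conditioning is what makes the
measure robust against *copies*: an inert node that duplicates a relay's
state would otherwise be indistinguishable from the relay itself, whereas in
the conditional measure a copy placed in `Y_0` absorbs ("shields") the
duplicated content. Two consequences are worth spelling out, because they
shape what fixtures can and cannot show:

* **Exclusion information.** With mutually exclusive classes, the relays of
  *other* classes always carry some information about class `i` (seeing
  class `j` fire rules out `i`). Conditioning them away therefore costs a
  little information even when the class-`i` relays are intact, so the
  greedy trajectory for a class is not perfectly flat outside its own
  relays on any multi-class task.
* **Duplicate preference.** If a relay has an exact copy, the pair
  `{relay, copy}` is the most informative two-node set under the
  conditional measure (neither member is shielded, and the complement
  contains no duplicate of their content). With two or more copies, once
  only duplicated content remains every further removal is equally
  catastrophic and the search's answer within that family is decided by the
  deterministic tie-break. Both behaviours are reproduced in the tests as
  the documented redundancy failure mode of the greedy search.

The *particular* relay information for class `i` replaces `Xin`/`Xout` with
the indicators `Z_i` and `Xout⁽ⁱ⁾`. `Xout⁽ⁱ⁾` is the argmax indicator (not
the binarized activation of output node `i`); this is configurable in
principle but the argmax readout is what defines the network's decision.

Entropies are plug-in (maximum-likelihood) estimates in base 2 over observed
tuples only. State tables may carry per-row probabilities, in which case the
"estimate" is the exact functional of the enumerated distribution; this is
how the distribution-level invariants (monotonicity over nested sets, greedy
= exhaustive optimality) are tested without tolerance. A Miller–Madow
bias correction (`+(K−1)/(2n ln 2)`) is available behind a flag and off by
default: the plug-in estimator is the measure the rest of the pipeline is
defined on, and the correction only shifts sampled estimates.

Empty relay set ⇒ `I_R = 0` by convention, which keeps the telescoping sum
of per-step losses over a complete removal trajectory exactly equal to the
full-set relay information.

## Subset search

`greedy_shrink` starts from `Y_R = Y`, evaluates `I_R(Y_R − a | Y_0 + a)`
for every candidate `a`, permanently discards the node whose removal
*retains* the most information (ties: lowest index), and repeats until
`Y_R` is empty — exactly `N(N+1)/2` evaluations. The full-set value that
seeds the trajectory is computed as a plain co-information, not counted as a
candidate evaluation. `exhaustive_search` enumerates all `2^N − 1`
bipartitions (hard cap 20 nodes, warning above 16) and reports *all* sets
tied for the per-size maximum within 1e-12, so redundant variants are
visible rather than collapsed.

The "minimal informative set" needs an operational definition; here it is
the smallest trajectory set retaining at least `(1 − ε)` of the full-set
relay information, with ε = 0.05 by default (exposed as a flag). ε = 0 is
meaningful only when every node outside the true relays carries strictly
zero information (the single-relay-channel fixture); on multi-class tasks
exclusion information makes the pair-level identification criterion the
removal rank / aggregated relay information instead, which is also how the
attribution matrices are meant to be read.

## Attribution

`ΔI(n)` is the loss at node `n`'s removal step; negative values can arise
from sampling noise and are reported unclipped. `I_A(n)` is the running sum
of `ΔI` in removal order, so the last node removed carries the full-set
information; this is the quantity that identifies synergistic sets whose
members individually look dispensable. Essentiality is
`I_R(Y) − I_R(Y∖n)` with *empty* conditioning on both sides. Dropping
rather than conditioning is deliberate: conditioning on `n` would charge the
node its individual co-information even when an exact duplicate remains in
the set, making a fully redundant node look essential. With the drop form,
inert nodes and duplicated nodes score exactly zero, and a node can rank
high on `I_A` while being non-essential — the signature of redundant
storage.

## Knockout analysis

A knockout zeroes a hidden node's incoming weights, bias, and outgoing
weights; because `tanh(0) = 0` this is bit-identical to clamping the
activation to zero mid-forward-pass (asserted exactly in the tests).
Randomised lesions are deliberately not offered: a noise-driven node is not
disabled, and a clamped non-zero constant interacts with the biases.

The knockout effect `K` of a node set for class `i` is the drop in class-`i`
recall (an overall-accuracy variant exists behind a flag). Note that a
knocked-out output sits at `tanh(bias)`, which can still win the argmax when
all competing outputs are strongly negative — `K` measures the realised
behavioural deficit, not the anatomical lesion size.

The validation panel knocks out every set along each class's greedy
trajectory (`N` sets per class; the empty set is excluded as identically
zero). The regression analysis fits ordinary least squares of `K` on
z-scored set size and z-scored particular relay information —
standardisation makes the two coefficients comparable — plus the two
single-predictor fits, whose r² values are the headline comparison. The two
single-predictor models are compared by the ratio of their residual sums of
squares (size-only over information-only), referred to an F distribution
with `(n−2, n−2)` degrees of freedom; values above 1 mean relay information
explains the knockout effect better than set size.

## Training

Networks are trained with Adam (defaults: learning rate 1e-3, batch 64,
β₁ = 0.9, β₂ = 0.999) on mean squared error against one-hot targets coded
±1 to match the tanh output range. Training stops at the first epoch whose
training accuracy reaches the target — 0.98 for one-vs-rest sub-networks
(trained with the native 1:(C−1) class imbalance, decision threshold 0),
0.96 for full classifiers — or at the epoch cap (500 / 200). The trainer is
plain numpy; with a fixed seed it is bit-reproducible. Composite networks
are assembled from sub-networks without further training; their
hidden-to-output matrix is exactly block-sparse, so output `i` depends only
on hidden slots `(2i, 2i+1)` — the ground truth that makes the composite a
positive control.

## Coarse-graining

Each hidden neuron is binarized independently. The default is a 1-D
two-cluster k-means: because the optimal two-cluster assignment in one
dimension is a threshold at the centroid midpoint, Lloyd iteration from the
(min, max) initialisation is deterministic and exact, with no seed
sensitivity. Cluster 0 is the lower cluster; a value exactly at the
threshold goes to cluster 0. A neuron whose activation range is ≤ 1e-9 is
treated as constant and mapped entirely to bit 0 (k = 2 is undefined on one
distinct value, and a constant column carries no entropy either way). The
median rule (threshold at the per-neuron median) is kept as the
maximum-entropy alternative. Binarizers are fitted on the same evaluation
set used for entropy estimation.

## Synthetic fixtures: what they emulate, and what they do not

`generate_pattern_dataset` stands in for an image-classification training
set: `C` mutually orthogonal ±1 prototypes (Hadamard rows, zero-padded to
the feature count), shrunk to ±(1 − a) and perturbed by uniform noise of
amplitude `a` (default a = 0.65), with optional label flips (default 0.005
in the pipeline). The defaults are chosen so the task is genuinely hard:
one-vs-rest sub-networks need on the order of ten to a few tens of epochs to
reach 0.98, which forces the output biases and rejection responses into the
saturated regime a long-trained classifier exhibits — at low noise the task
is solved in two epochs and the barely-moved biases make knockouts nearly
ineffective. What the generator does *not* emulate: pixel correlations,
within-class style variation, and the graded between-class similarity of
real images (prototypes are orthogonal, so cross-class responses are more
uniformly negative than for, say, easily confused numerals). Knockout
effects and cross-class information are correspondingly cleaner than in real
data; passing tests demonstrate the machinery's correctness and the
direction of the effects, not their real-data magnitudes.

`make_planted_relay_network` is the analytic control. Class 0 is a
featureless background class that wins the argmax whenever no relay pair
fires; each real class `i` owns the hidden pair `(2(i−1), 2(i−1)+1)`. The
two relays are gated on private ±1 "coin" inputs (r1 fires on the class
prototype with coin `a` up; r2 with `a` down and `b` up), giving joint
coverage 3/4. This specific construction solves three problems at once:
the prediction is an exact function of the *binarized* hidden state (so the
full-set identity holds exactly); no bipartition's complement determines a
class indicator (a "perfect" composite would make every conditional relay
information collapse to zero); and the two relays are complementary rather
than copies, so each planted pair is the unique two-node maximum of the
exhaustive search. Decision margins are at least ±gain/4 (gain default 16),
and per-node gains carry a seeded ±5 % jitter so different seeds break ties
differently without ever changing a margin's sign. Inert nodes (all-zero
weights) and redundant copies (duplicated incoming weights, zero outgoing)
can be appended to probe `ΔI = 0` and zero essentiality. Because hidden
states are functions of the discrete `(class, coins)` state, the exact joint
table is enumerable (capped at 2^16 states).

## Problem sizes

The self-contained composite experiment used by the pipeline, the test
suite, and the acceptance script runs at 10 classes × 16 features ×
2,500–4,000 samples with 20 hidden nodes — large enough that sub-networks
train for tens of epochs and the 2^6–2^8-state exact fixtures are
enumerable, small enough that a full analysis (training, coarse-graining,
ten greedy searches of 210 evaluations each, a 200-record knockout panel,
and the regression) completes in well under a minute on one CPU. Exhaustive
searches in tests use 4–10 hidden nodes.

## Known limitations

* One hidden layer, tanh units, argmax readout only; no convolutional,
  recurrent, or multi-layer variants, and no differential-entropy path for
  continuous states.
* The greedy search is the un-branched variant; under heavy redundancy it
  returns one member of the tied family (deterministically, via the
  tie-break) and can fall below the exhaustive per-size maximum once only
  duplicated content remains.
* Plug-in entropies are biased at small sample sizes; the per-class
  indicator channels keep the effective state space small, but ΔI values
  near zero should be read with the estimator noise in mind.
* Essentiality considers single-node drops only; a node essential only
  jointly with another will not be flagged.
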