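# Methods

`chunkwm` simulates a prefrontal-cortex / basal-ganglia working-memory
(PBWM) circuit augmented with an adaptive chunking layer, performing a
continuous-report color-wheel task. This note documents the model, the
constants it runs with, the reasoning behind the design choices the
underlying circuit description leaves open, and what the simulations do
and do not establish.

## Task

An episode presents `set_size` (2–4) colored, oriented bars one at a
time: each store trial carries a color drawn uniformly from the wheel
([0, 2π)) and a discrete orientation (4 possible, distinct within an
episode). A recall trial then shows one presented orientation alone,
and the network must reproduce the color bound to it. Reward is linear
in the circular report error, `r = 1 − |err°|/45`, positive within 45°,
bounded below at −1 (so maximal punishment equals maximal reward in
magnitude); a non-response — no stripe output-gated, or an undecodable
output — is scored by substituting a uniform random report. Training
runs in epochs of 100 trials (store and recall events both count).
Working memory and eligibility traces are cleared between episodes.

## Rate neurons and inhibition

Every layer uses rate-coded point neurons. The membrane potential
integrates excitatory, inhibitory, and leak currents toward the
conductance-weighted mean of the reversal potentials (explicit Euler,
dt = 0.15 on a unit time constant, per-step rate clamped at 1 so the
update is always a convex combination — membrane potentials can never
leave the reversal-potential range). The emitted rate is a thresholded
sigmoid of the excess excitatory conductance over the threshold
conductance geΘ(gi): `y = γz/(1 + γz)` with `z = [ge − geΘ]+`, γ = 100.
Constants are the standard normalized set: E_e = 1, E_l = 0.3,
E_i = 0.25, Θ = 0.5, ḡ_l = 0.1.

Net input is the fan-in-normalized mean of sender activity times
weight, per projection; converging projections combine as a
rel_scale-weighted average in which silent projections still occupy
their share of the normalization (so drive does not inflate when a
source is empty). One-to-one topographic projections therefore pass
their sender through at full strength.

Each layer has a single inhibitory pool: `gi = Gi·(ff + fb)` with
feedforward inhibition from the layer's mean net input (floor 0.1,
below which ff is 0) and feedback inhibition from an exponential
average (rate 0.7/cycle) of the layer's mean firing rate; the averaging
prevents inhibitory oscillation in small layers. Settling iterates net
input → inhibition → membrane → activation with activation steps damped
by 0.5, to a fixed cycle budget (30–40 depending on the layer) with
early stop when activity changes fall below 1e-4. Where all senders
into a layer are clamped for a trial phase, the production code
iterates only the inhibition pool and the rate code — the fixed point
is identical (cross-checked in the test suite) because the rate code
depends only on (ge, gi).

## Population code

Colors are coarse-coded as circular-Gaussian bumps over 20 units with
evenly spaced preferred colors; σ = 0.73 rad puts roughly 10 of 20
units above a 0.1 activity floor. Decoding is the population vector
(angle of Σ y_k·e^{i·pref_k}), with the normalized resultant length as
a confidence; resultants below 0.1 at the output layer count as
non-decodable and hence as non-responses. Signed errors live in
(−180°, 180°], ties at 180° mapping to +180°. The encode/decode
round-trip is accurate to < 2°; the settled attractor dynamics add a
few degrees of discretization error because the steep rate threshold
snaps bump edges to unit boundaries.

## Chunk layer

A posterior ring layer receives the sensory bump through a topographic
projection (rel_scale 2) and each PFC stripe's maintained bump through
weaker topographic projections (rel_scale 1 each; both stripes project
throughout the episode), with pooled inhibition Gi = 2.0, ff floor
0.05. Convergent excitation pulls the settled bump toward a maintained
representation that overlaps the input; inhibition thresholds away
non-overlapping PFC bumps. The resulting attraction profile is zero at
zero offset, peaks near 60° offset (~17° deviation), and returns under
2° beyond ~140° — the 2:1 scale ratio and inhibition gain were fixed,
once, to put the peak in the 20–60° band. Only the nearest maintained
bump matters: adding a second, distant bump changes the merge by < 2°.

## Stripes and gating

PFC is divided into independently gateable stripes; each has a
transient superficial layer mirroring its source (the raw input, or
the chunk layer — a chunk model has exactly one chunk-linked stripe),
and a deep maintenance layer that holds gated content without decay.
Striatal Go/NoGo modules (one per stripe per gating type) read a
control vector: one-hot orientation (4 bits), store/recall phase
(2 bits), and the stripe's own empty/occupied state (2 bits). A gate
fires when the noisy Go − NoGo drive (Gaussian exploration noise)
exceeds zero; input gating loads superficial content into maintenance
(overwriting), output gating at recall copies maintenance to the
output side. Gates compete within a gating type, standing in for
pallidal/thalamic selection: each drive is reduced by a fraction of
the strongest rival positive drive — 0.75 on the output side (usually
one representation is read out, near ties still gate several stripes
in parallel, the mechanism behind "contaminated" averaged responses in
over-provisioned networks) and 0.5 on the input side (mild: several
stripes can still load the same stimulus, but an occupied stripe tends
to lose the update to an empty rival). The competition also
decorrelates the stripes' firing histories; with fully independent
thresholds and a single shared RPE, all stripes of a network receive
identical eligibility streams once their drives saturate and their
policies cannot differentiate at all. The response layer receives the
mean of all gated-out bumps.

Exploration noise anneals exponentially from 0.15 to 0.08 over the
first 60% of training and stays at 0.08 for the remainder and for
evaluation; early training explores gating strategies, late training
exploits the learned contrast, and evaluated behavior remains
stochastic.

## Reinforcement learning

A Rescorla–Wagner critic tracks expected reward (α_V = 0.05) and emits
a reward prediction error at each recall. The critic starts at the
reward floor (V₀ = −1): early outcomes then arrive as positive
prediction errors, which keeps gating alive while the readout pathway
is still untrained. Dopamine scales the RPE asymmetrically — bursts by
burst_gain (0.6), dips by dip_gain (0.6) after clipping the RPE at
−0.65, reflecting dopamine's bounded range below baseline. The clip is
load-bearing twice over: without it, the rare failures of a
high-performing policy carry RPEs an order of magnitude larger than
its many small successes and the policy erodes itself; and its value
sets where progressive disengagement ("giving up") begins as task load
grows.

Each gating decision leaves an eligibility tag: fired gates stamp the
control vector on the Go side, silent gates on the NoGo side. Tags
saturate at 1 per synapse (so control bits active on every trial do not
accumulate disproportionate credit), decay by 0.9 per trial, and clear
after each RPE. At reward time, Go-tagged synapses move with the
effective RPE and their NoGo opponents against it; NoGo-tagged (silent)
synapses move opposite to the RPE at a quarter of the rate
(omission_scale = 0.25) — dips reinforce learned suppression (the
give-up mechanism), bursts produce LTD on active NoGo synapses (the
recovery path). Striatal learning rates are 0.005 with slow
multiplicative forgetting (0.001 per reward event) that bounds the
windup of unused weights; the equilibrium weight contrast is the ratio
of reinforcement to forgetting. Weights stay in [0, 1].

The gating policy is summarized per stripe by the rectified normalized
Go−NoGo contrast over the orientation-block weights,
α_j = [(ΣGo − ΣNoGo)/(ΣGo + ΣNoGo)]+.

## Supervised readout

Two plastic mappings drive the 20-unit output layer (Gi = 1.0): the
direct input→output map, trained on every store trial to reproduce the
presented color, and the PFC-output→output map, trained on recall
trials whenever content was gated out, toward the probed item's true
color. Both use a two-phase contrastive delta rule (settled output vs
output clamped to the encoded target; learning rate 0.2) with soft
weight bounding (LTP ∝ 1−w, LTD ∝ w) — without the soft bounds, early
recalls that read out the wrong stripe pair presynaptic bumps with
uncorrelated targets and ratchet the whole matrix to its ceiling. All
other projections are fixed. The direct map generalizes across the
wheel from a handful of training colors because the population code is
topographic and smooth.

## Analyses

Error histograms are decomposed with a two-component mixture — uniform
(guessing) plus zero-centered von Mises (memory) — fit by EM; κ is
floored at 2 because a near-flat von Mises trades off arbitrarily with
the uniform component on guess-heavy data. Stripe usage and
empty-stripe ("giving up") rates are measured on maximal-load store
trials; out-of-cluster variance (OCV) is the circular standard
deviation, in degrees, of the non-probed items' colors; recency curves
bin recall error by the number of trials since the probed item was
presented. The combinatorial baseline for random gating,
(n−1)^(N−1)/n^N for n stripes and N items, is verified against
exhaustive enumeration of all input-gate assignments and output-gate
choices. The printed single-item baselines (50% for two stripes, 33%
for three) correspond to N = 1 in this formula — the only value
consistent with both printed numbers, although the surrounding
narrative discusses multi-item sets; the implementation exposes N
explicitly rather than reinterpreting the formula.

## Problem sizes

The reference conditions are 500 epochs × 100 trials with 80+ random
seeds per configuration. The packaged batteries are scaled down: the
acceptance script trains 10 seeds per model at set size 2 and 8 per
model at set size 4, for 250 epochs; the test suite's shared battery
uses 10 seeds × 100 epochs, and the dopamine sweep 2 seeds × 60 epochs
per cell on a 3×3 gain grid. These scales are past the point where the
gating policies stop changing qualitatively; quantities that are
averages over stochastic trials (usage rates, output-gate counts,
non-response rates, mixture weights) are correspondingly noisier than
at the reference scale.

## What the simulations show, and what they do not

The synthetic task generator reproduces the structure of delayed-
estimation color experiments — sequential presentation, uniform
colors, orientation-keyed probes — but not their perceptual front end:
orientations are symbolic one-hot codes, there is no encoding noise,
no delay-period noise, and maintenance is lossless by construction, so
forgetting in the model is entirely a gating phenomenon (overwriting,
chunk-merging, or failure to gate), never passive decay. Chunking
advantages, giving-up under load, dopamine-balance effects, and
recency effects are therefore statements about the credit-assignment
dynamics of gating policies, not about sensory precision. Within-trial
binding errors of human observers map only onto the model's
wrong-stripe readouts. The learned policies at this scale solve the
binding problem imperfectly (median recall error at set size 2 is
~30°, dominated by swap errors rather than imprecision); the
comparative results between chunk and control models, which are what
the analyses interpret, are robust to this.

At desk scale the learned binding remains partial, and this shapes
which comparative phenomena are crisp and which are diluted: the
chunk-vs-control orderings of guess mass, central density, stripe
usage, and recency are robust, while effects that require mostly
correct readout before they can express themselves — the
out-of-cluster-variance gating of the chunking advantage, the graded
chunk-vs-input gating-policy contrast, and the symmetric-dopamine
optimum at set size 2 — are weakened or absent. The test suite states
each of these as the directional claim and lets it fail where the
desk-scale model does not reproduce it.

## Known limitations

* One chunk layer with fixed top-down strength: the chunking criterion
  is not itself learned (a single effective chunking threshold).
* The striatal actor is condensed to per-stripe Go/NoGo threshold
  units over an 8-bit control vector; pallidal and thalamic stages are
  represented by the threshold-plus-competition rule, not by unit
  dynamics.
* The error-driven readout rule is a contrastive delta rule, not a
  full temporally extended XCAL implementation.
* A single global critic; no within-episode temporal-difference
  chaining.
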