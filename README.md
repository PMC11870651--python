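# chunkwm

A simulator of working-memory gating in a prefrontal-cortex /
basal-ganglia (PBWM) circuit augmented with an adaptive **chunking**
layer, together with a continuous-report color-wheel task harness and
an analysis suite.

## The scientific problem

Visual working memory is limited, but the limit does not behave like a
fixed number of slots: people trade precision for quantity, and their
effective capacity depends on how well they *manage* storage — which
items to encode, where, and what to read out when probed. This package
implements a neural-circuit account of that management problem:

* Colors are stored as Gaussian activity bumps over ring-coded neural
  populations, maintained without decay in isolated PFC **stripes**
  (independently gateable memory slots).
* Striatal **Go/NoGo** modules decide, per stripe, whether to load the
  current stimulus (**input gating**) and which maintained content to
  read out at recall (**output gating**). These gating policies are
  not wired in: they are learned from reward prediction errors (RPEs)
  conveyed by dopamine bursts and dips, with eligibility traces
  assigning credit to recent gating decisions.
* A posterior **chunk layer** receives the sensory bump and weaker
  top-down projections from every maintained stripe; when the incoming
  color is close to a stored one, convergent excitation and lateral
  inhibition merge the two into a single, less precise "chunk" that a
  dedicated stripe can store — freeing the other stripe(s) for other
  items, at a cost in precision.

The central objects are the gating policy per stripe *j*,

    alpha_j = [ (sum Go_j - sum NoGo_j) / (sum Go_j + sum NoGo_j) ]+

(the rectified, normalized corticostriatal weight contrast over the
orientation inputs), and the success probability of purely *random*
gating with `n` stripes and set size `N`,

    P = (n - 1)^(N - 1) / n^N,

which quantifies why the credit-assignment problem gets harder, not
easier, as more stripes are allocated.

## Worked example

Train a two-stripe chunking network on set-size-2 episodes and look at
its summary:

```bash
chunkwm train --model chunk --set-size 2 --epochs 250 --seed 1 \
    --out runs/chunk-ss2
```

which prints (this exact output, seed 1):

```json
{
  "all_stripes_occupied": 1.0,
  "central_density": 0.41,
  "empty_stripe_rate": 0.0,
  "final_alphas": [
    0.9916766237384133,
    0.9916769093061248
  ],
  "guess_weight": 0.6030338198622744,
  "mean_abs_error_deg": 50.555930663764414,
  "mean_output_gated": 1.0,
  "median_abs_error_deg": 25.40708406767193,
  "model": "chunk",
  "non_response_rate": 0.0,
  "seed": 1
}
```

Reading: after training, every maximal-load store trial leaves both
stripes occupied (`all_stripes_occupied` = 1.0), the network reads out
exactly one stripe per recall (`mean_output_gated` = 1.0) and always
responds. 41% of recalls land within 15° of the true color
(`central_density`); the mixture fit assigns the remaining broad
errors — mostly swaps, i.e. reading out the stripe holding the other
item — to its uniform component (`guess_weight`). Both stripes'
input-gating policies ended strongly Go-dominated (`final_alphas`).

Analyses over one or more runs:

```bash
chunkwm analyze runs/chunk-ss2 --analysis histogram   # binned errors
chunkwm analyze runs/chunk-ss2 --analysis recency     # error vs lag
chunkwm analyze runs/chunk-ss2 --analysis usage       # stripe occupancy
chunkwm profile                                       # chunk-layer merge profile
```

The library surface mirrors the circuit: `chunkwm.neurons` (rate
neurons, FFFB inhibition, settling), `chunkwm.popcode` (bump
encode/decode), `chunkwm.chunk` (the merging layer),
`chunkwm.circuit` (stripes, gating, the full network),
`chunkwm.learning` (critic, dopamine, striatal plasticity),
`chunkwm.readout` (supervised response pathways), `chunkwm.task`
(episodes, scoring, OCV), `chunkwm.experiments` (training loops and
all analyses). See `docs/methods.md` for the model description and
parameter rationale.

## RunLog schema

`train` writes per-trial CSVs with columns: `epoch, trial, kind,
orientation, target, reported, error_deg, reward, delta, non_response,
n_output_gated, lag, ocv, store_index, occ0..occ{n-1}` (occupancy after
the trial's gating), plus per-epoch `alphas.csv` (`epoch, stripe,
source, alpha`) and a frozen-weight evaluation log `eval.csv` with the
same trial schema.

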