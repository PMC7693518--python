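# Methods

## Problem and pipeline

`spikecube` classifies short, raw (feature-free) EEG segments into low/high
valence or arousal using a spiking neural network of the NeuCube family.  The
chain has four stages:

1. **Spike encoding** — threshold-based representation (TBR) turns each
   channel of a segment into a signed event train.
2. **Reservoir** — events drive a 3-D cube of 1000 leaky integrate-and-fire
   (LIF) neurons wired by a distance-limited random rule, trained without
   labels by spike-timing-dependent plasticity (STDP).
3. **State read-out** — per sample, each cube neuron's first-spike time and
   spike count are recorded.
4. **deSNN output layer** — one output neuron per training sample, whose
   weight over cube neurons is `mod^rank` by first-spike order plus a drift
   term per extra spike; test samples take the label of the nearest output
   neuron (Euclidean, k = 1).

The input layout is the DEAP convention: per participant a
40 trial x 32 channel x 8064 point array at 128 Hz (63 s trials, 4-45 Hz
passband applied upstream) and a 40 x 4 table of self-report ratings in
[1, 9] for valence, arousal, dominance and liking.  Experiments use four
channels (FP1, F3, C4, C3), a 1152-point window starting 34 s into each
trial, labels binarised at rating 5 (high iff rating >= 5), and a seeded
stratified 80/20 train/test split.  The nominal "34 s to 42 s" span would be
1024 points at 128 Hz; the stated point count 1152 (9 s) is taken as
authoritative because it fixes all downstream shapes, so the window ends at
43 s.

Named subsets: Exp1 = trials 1-10 of participants 1-6 (60 samples),
Exp2 = trials 1-10 of participants 1-4 (40), Exp3 = trials 11-20 of
participants 7-12 (60), Exp4 = the first 40 samples of Exp3's enumeration.
Note that 20% of 60 is 12 test samples under floor-based splitting; published
accuracies of the form 11/13 on 60-sample sets imply a 13-sample test set
whose construction is not documented, and no attempt is made to match it.

## Parameters

Reference values (kept as package defaults):

| parameter | value | stage |
|---|---|---|
| TBR threshold factor | 0.5 | encoding |
| cube size N | 1000 (10 x 10 x 10 grid, unit spacing) | reservoir |
| small-world radius | 2.5 grid units | reservoir |
| firing threshold | 0.5 | reservoir |
| STDP learning rate | 0.01 | reservoir |
| modulation factor `mod` | 0.8 | classifier |
| drift | 0.005 | classifier |
| train fraction | 0.8 | split |

Free parameters (not published for the reference implementation; chosen here
once and config-exposed):

| parameter | default | rationale |
|---|---|---|
| leak | 0.1 / step | membrane time constant ~74 ms at 128 Hz, in the biophysical 10-100 ms range; see below |
| refractory | 3 steps (~23 ms) | caps a neuron's rate at 1 spike / 4 steps, preventing runaway |
| connection probability | 0.15 | ~12 outgoing connections per interior neuron (~80 neighbours within 2.5) |
| inhibitory fraction | 0.25 | stabilising; within the cortical 15-30% range |
| initial weight scale w0 | 0.2 | magnitudes uniform on (0, w0] scaled by 1/distance |
| weight cap | 1.0 | one potentiated synapse can relay a spike (cap >= threshold) |
| input gain | 1.0 | one external event can fire an input site directly |

### The operating point of the cube

The cube's dynamics have a sharp bistability in this parameter family: with a
very long membrane memory (e.g. leak 0.002/step, i.e. a ~4 s time constant)
and a 1-step refractory period, recurrent excitation self-sustains — roughly
450 of 1000 neurons fire on every step regardless of the stimulus — while
slightly weaker coupling leaves the cube silent beyond the four input sites.
Neither regime transmits stimulus information, and in the saturated regime
the first-spike pattern and spike counts are identical across classes.  The
defaults above (leak 0.1, refractory 3, w0 0.2, 25% inhibition) hold the cube
in an input-locked sparse regime: activity is driven by the encoded events,
propagates locally around the input sites, and STDP potentiates the causal
pathways without igniting the network.  The choice was validated by the
stimulus-selectivity property (between-class cube-state distance exceeding
within-class distance across seeds), not by any single benchmark number.

### Dynamics contract (exactly testable)

Per step `t`, in order: membrane decay `u <- u * (1 - leak)`; recurrent input
from neurons that fired at `t-1` through the current weights; signed external
input at the mapped channel sites; refractory neurons clamped to `u = 0`;
firing at `u >= threshold` with reset to 0 and a refractory counter.  The
membrane has no lower floor, so inhibition and negative input events can
drive it below rest.  During STDP, for each existing connection i -> j:
|w_ij| += rate when i fired at `t-1` and j fires at `t`; |w_ij| -= rate when
j fired at `t-1` and i fires at `t`; magnitudes clip to [0, w_cap];
potentiation is applied before depression within a step; connection sparsity
and signs are fixed at initialisation.  A naive dict-and-fsum reference
simulator in the test suite reproduces spikes and post-STDP weights
bit-for-bit on small cubes.

Tie-breaks are deterministic everywhere: rank ordering resolves first-spike
ties by lowest neuron index; nearest-neighbour classification resolves
distance ties by lowest output-neuron index and vote ties by the single
nearest neighbour.  Degenerate inputs are defined, not fatal: constant
channels encode to zero events; a record with no spikes yields an all-zero
state vector with a warning; an all-zero test vector still classifies by
distance.

### TBR threshold semantics

The published factor 0.5 is interpreted relative to each channel's own
difference statistics: theta = 0.5 * sd(|x(t) - x(t-1)|), computed per
channel per sample.  This makes encoding invariant to amplitude scaling
(x -> c x for c > 0), so synthetic signals and differently-scaled recordings
behave identically.  An absolute mode (theta in signal units) is available;
both are documented approximations of the reference encoder, whose exact
normalisation is not published.

## Synthetic data: what it emulates, what it does not

The generator reproduces the DEAP *layout* exactly — shapes, 128 Hz sampling,
10-20 channel names in DEAP order, rating ranges — with a controllable
two-class signal: each trial draws a class on one dimension, and its EEG is a
class-specific sinusoid (default 10 Hz, inside the 4-45 Hz passband; random
phase per trial; amplitude jittered per trial) identical on all channels,
plus white Gaussian noise independent per channel.  Ratings on the generated
dimension come from the class's Gaussian clipped to [1, 9]; the other three
columns are uniform.

Defaults: low class amplitude 0.5, high 1.5, noise sd 0.5, jitter sd 0.1,
rating means 3/7 with sd 1 (clearly separated around the threshold 5).  The
"strongly separated" condition used by the end-to-end checks fixes amplitudes
0.2 / 2.0, noise 0.2, no jitter, ratings exactly 2 / 8.

The generator deliberately omits: volume conduction and channel covariance,
1/f background spectra, artifacts (EOG/EMG), non-stationarity, and any
realistic forward model.  Passing tests therefore demonstrate that the
pipeline transduces and classifies a known narrow-band amplitude difference
end to end — not that it reaches any particular accuracy on recorded EEG.
Real DEAP recordings (access-restricted) can be consumed through the
provided `.dat` adapter, but no result on them is claimed or tested.

## Problem sizes used by tests and the acceptance script

Structural checks generate the full 32-participant DEAP shape once; dynamics
oracles run 27-neuron cubes for 50 steps; end-to-end checks run the complete
60-sample Exp1 configuration at the full 1000-neuron, 1152-step scale, with
5 seeds for the separable condition and 10 for the shuffled-label null.
Property tests on small cubes (125 neurons, 384-point windows) cover the
selectivity invariant across seeds.

## Known limitations

- The reference software's encoder normalisation, STDP kernel, and state
  read-out are not published; the contracts above are this package's own,
  chosen to be deterministic and exactly testable.
- One STDP pass in training order; no convergence criterion.
- The deSNN layer stores one neuron per training sample (memory grows
  linearly with the training set; fine at n <= 48).
- Binary classification only; no multi-class or regression read-out.
- The split is stratified by default (the tiny sample sizes otherwise often
  produce single-class test sets); an unstratified mode exists.
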