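# Methods

## Model

Each brain region `i` is a phase oscillator coupled through the structural
connectome:

    dθ_i/dt = Ω_i + λ Σ_j W_ji sin(θ_j − θ_i)

`W` is a symmetric, non-negative, zero-diagonal weight matrix (normalized
by its global maximum by default; a mean-strength mode is available).
`Ω_i` is the region's natural frequency. Under the default `two-pi`
angular convention a profile given in Hz is converted to rad/s
(`Ω = 2πω`), so a region oscillates at its nominal frequency; a `literal`
convention treats the Hz value as an angular rate directly. The coupling
λ is not transferable between conventions and must be (re-)calibrated
under whichever one is used.

Natural frequencies encode a hierarchy of intrinsic timescales: they
decrease with anatomical node strength `s_i = Σ_j W_ji`,

    ω_i = b − (b − a) · ((s_i − s_min) / (s_max − s_min))^γ

with defaults `a = 0.01 Hz` (slow bound, assigned to the strongest hub),
`b = 0.1 Hz` (fast bound, weakest node) and `γ = 2`. These bounds bracket
the slow BOLD fluctuation band; all three are configurable. The mapping
depends only on each strength's normalized position between the extremes,
so it is invariant to any uniform rescaling of `W` — in particular the
choice of normalization mode does not affect the frequency profile.

The BOLD proxy is `sin θ_i`, sampled every 2.25 s (a typical fMRI
repetition time) after discarding a 2.12-minute transient from each
8-minute run. Functional connectivity (FC) is the Pearson correlation of
these sampled series; seed FC is one region's correlation with every
other region. No hemodynamic convolution is applied: at 0.01–0.1 Hz the
oscillator abstraction is the object of study, not a forward model of
the scanner signal.

## Virtual inhibition

Inhibitory stimulation of a region is modelled as a reduction `Δω` of its
natural frequency. A *trial* runs the baseline and the perturbed system
from identical uniform-random initial phases (trial seed = base seed +
trial index). This paired design makes the `Δω = 0` null exact — the two
runs are the same computation — and cancels most between-trial variance
from the effect estimate. Within a sweep the baseline ensemble is shared
across all grid points.

Sweeps aggregate, per grid value, the across-trial mean (± s.e.m.) of the
average change in the target's seed FC. Changes are computed on the
Fisher-z scale by default (`raw` optional); correlations are clipped at
magnitude `1 − 1e−12` before `atanh` so numerically perfect correlations
cannot produce infinities. Per-region inference uses the two-sided
Wilcoxon signed-rank test across trials with Bonferroni correction over
the N−1 non-target regions.

Calibration selects λ from a grid by maximizing the Pearson correlation
between the simulated across-trial mean seed-FC vector(s) and a reference
vector — in this package a model-generated reference, which turns
calibration into a parameter-recovery exercise with known ground truth.

## Numerical choices

- Integrator: Heun (2nd order), default `dt = 0.05 s`. For the default
  frequency band and couplings the drift per step is ≪ 1 rad; halving
  `dt` moves sampled phases by < 1e−3 rad. Strong-coupling regimes
  (λ·strength approaching 1/dt) need a smaller step; the integrator
  raises on non-finite phases rather than returning garbage.
- Ensembles are integrated as one batched matrix product over trials;
  each trial's column evolves independently. Baseline and perturbed
  ensembles run as two same-shaped calls so the null case is bitwise
  reproducible.
- Signed-rank test: the exact null is computed by subset-sum convolution
  over doubled mid-ranks (equivalent to enumerating all 2^n sign
  assignments) for n ≤ 25 effective pairs, a normal approximation with
  tie and continuity corrections above. Note the exact null at n = 15 is
  discrete with probability jumps near 0.01 around its center, so exact
  and approximate p agree to < 0.005 in the decision-relevant tail
  (p < 0.05) but not uniformly — a limitation of any continuous
  approximation, not of the implementation.
- ALFF: mean of the one-sided amplitude spectrum `(2/T)|DFT|` of the
  demeaned series over bins inside the band (default 0.01–0.1 Hz). The
  DC bin is excluded by construction; no detrending beyond mean removal,
  as the simulated signals are stationary.
- Sparsification keeps the `⌈density · N(N−1)/2⌉` largest undirected
  edges; ties at the cutoff are resolved by lexicographic `(i, j)` order
  so results are reproducible.
- "Fiber distance" is proxied by Euclidean distance between region
  centroids; true tract lengths would require the tractography geometry.
- Perturbations tolerate `Δω` exceeding the target's frequency by up to
  1e−12 (clamping at zero), because the mapping assigns the strongest hub
  exactly the slow bound up to float rounding and the sweep grid's top
  point equals that bound.

## Synthetic study conditions

No empirical connectome is shipped; the generator produces the study's
inputs. It emulates the features the experiment needs, not anatomy:

- modular topology (stochastic-block-like; 4 modules of 32 regions by
  default) with intra/inter connection probabilities 0.7 / 0.35, giving
  ~45% edge density so that a 30%-density sparsified variant genuinely
  prunes edges;
- heavy-tailed weights: log-normal edge weights scaled by the geometric
  mean of log-normal per-node gains (σ = 0.45), giving a right-skewed
  strength distribution;
- one designated hub whose gain is 3× the largest plain-node gain (its
  strength tops the distribution, hence ω_hub = a) and one designated
  sensory node damped to the bottom of the strength range (hence
  ω_sensory ≈ b). With the defaults the sensory-minus-mean frequency gap
  is ≈ 0.004 Hz, inside the 1e−5–1e−2 Hz sweep span, so the sweep can
  cross the mean-matching point;
- module centroids on a 40 mm lattice with 8 mm within-module jitter, so
  distance correction rescales long-range edges without erasing the
  hub's strength dominance;
- determinism: identical spec (including seed) gives identical output;
  disconnected components, if sampled, are bridged deterministically
  through the hub. Hub/sensory strength-percentile contracts are
  verified before returning.

The default coupling for this connectome is `SYNTHETIC_COUPLING = 0.07`
(two-pi convention, global-max-normalized weights), fixed once by the
calibration procedure. In this regime the network bulk is strongly
synchronized while the far-detuned hub and the fast sensory node remain
imperfectly entrained — the configuration in which slowing the sensory
node toward the network mean raises its FC with the rest of the network
(peaking where its frequency matches the mean) and slowing the
already-slow hub lowers its FC or deepens anticorrelations. The same
directions hold for the sparsified and distance-corrected variants at
this coupling. The 16-region toy network used in fast tests is smaller
and weaker-coupled internally; it sits in the analogous regime near
coupling 0.5.

What passing tests show — and don't. The synthetic connectome reproduces
the *structural* preconditions of the empirical analysis (hub/periphery
strength contrast, heavy tail, modularity) and the experiments reproduce
the *qualitative* phenomena (effect directions, peak at the mean
frequency, robustness to matrix variants, control-site specificity).
They do not reproduce any particular parcellation's strength
distribution, the printed empirical frequencies or model–data fit
correlations, which depend on an unavailable tractography matrix and
participant recordings.

## Problem sizes

Default experiment conditions: 128 regions, 100 paired trials per grid
value, a 12-point logarithmic Δω grid spanning 1e−5–1e−2 Hz, 8-minute
trials at `dt = 0.05 s`. Calibration-recovery runs use a 64-region
network and a factor-2 coupling grid; robustness checks probe one
moderate Δω per target. Larger sizes (e.g. 513 regions, 500 trials) are
reachable through the same configuration objects.

## Known limitations

- The observable `sin θ` with Pearson correlation is one of several
  reasonable FC readouts for phase models (instantaneous phase coherence
  is another); results here are tied to that choice.
- Trials differ only in initial phases; the integrated system is
  deterministic (no dynamical noise process).
- In a deterministic paired design, arbitrarily small systematic effects
  become significant as trials accumulate; "no modulation" statements
  are therefore made against the Bonferroni-corrected threshold and an
  effect-size comparison, not raw p > 0.05.
- Euclidean centroid distance underestimates true fiber length,
  especially between nearby regions connected by curved tracts.
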