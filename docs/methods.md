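# Methods

## Scope and pipeline

`plinet` re-implements, as a tested pipeline, a resting-state EEG network
analysis for small clinical cohorts (here: nonfluent/agrammatic primary
progressive aphasia, agPPA, vs primary progressive apraxia of speech,
PPAOS): band-limited epoching, phase-lag-index (PLI) functional
connectivity, weighted graph-theory and minimum-spanning-tree (MST)
summary measures, and nonparametric group/brain-behavior statistics.
Patient EEG of this kind is not publicly deposited, so the package ships a
coupled-oscillator simulator that generates cohorts with known coupling
structure and planted measure-behavior associations; every pipeline stage
is validated against analytic values, brute-force oracles, or Monte-Carlo
ground truth from that simulator.

## Preprocessing

- **Bands**: theta 4-8 Hz, alpha1 8-10 Hz, alpha2 10-13 Hz. Band edges are
  passband corners; adjacent bands share the boundary frequency.
- **Filter**: 4th-order Butterworth band-pass applied forward-backward
  (`sosfiltfilt`), i.e. zero-phase with an 8th-order magnitude response.
  Zero phase matters because any phase distortion would bias the
  phase-difference statistic downstream. The continuous recording is
  filtered *before* segmentation so filter transients live at the
  recording ends, not inside every epoch.
- **Epochs**: non-overlapping 1024-sample segments from sample 0
  (4.000 s at 256 Hz); the trailing remainder is discarded.
- **Artifact screen**: an epoch is flagged if any channel exceeds 100 uV
  absolute amplitude, has peak-to-peak below 0.1 uV (flat line), or has a
  variance more than 5 SD above that channel's across-epoch mean. These
  are conventional, configurable stand-ins for the visual gestalt
  screening used on clinical recordings; they are deliberately simple
  (no ocular regression or ICA).
- **Selection**: exactly 8 clean epochs, earliest-first by default
  (`random` with a seed is available). Fewer than 8 clean epochs is a
  hard error that names both counts.

## Connectivity: phase lag index

Phases come from the analytic signal (Hilbert transform) of each
already-filtered epoch, without extra tapering: at 4 s per epoch the
band period is short relative to the segment and continuous-recording
filtering already controls transients. For channels i, j:

    PLI_ij = | mean_t sign( wrap(phi_i(t) - phi_j(t)) ) |,

with the difference wrapped into (-pi, pi] and sign(0) counted as 0 (the
denominator stays fixed at the sample count). PLI is 1 iff the sign of
the lag is constant and nonzero, 0 for consistently zero-lag
(volume-conducted) synchrony, and is invariant to channel amplitude
scaling. Per-epoch matrices are combined by element-wise mean across the
8 selected epochs (not PLI of the concatenated epochs).

**Small-sample bias.** Because the absolute value sits inside the
per-epoch average, the estimator has a positive floor for uncoupled
channels: a 2-Hz-wide band gives roughly 0.5 s of phase coherence, so a
4-s epoch contains only ~8 independent sign stretches and the per-epoch
|mean sign| of independent narrowband channels averages ~0.3; averaging 8
epochs keeps that floor (~0.36 on simulated uncoupled pairs) rather than
shrinking it. This is a property of the estimator as used in the field —
empirical whole-scalp PLI medians around 0.19-0.25 in 21-channel studies
sit at exactly this kind of floor — and it is why the simulator's
cohort-level defaults operate above it (below). The *pooled* sign average
(signs concatenated across epochs before taking the absolute value) does
converge to 0 for uncoupled channels and is used in tests to verify the
estimator's consistency, but the pipeline reports the per-epoch-mean
variant.

## Network measures

All measures take a symmetric nonnegative matrix W with zero diagonal.

- **Mean PLI**: mean of the N(N-1)/2 upper-triangle entries.
- **Weighted clustering C_w** (triple-product ratio, the Brainwave-lineage
  variant; an Onnela-style geometric-mean variant is selectable):
  C_i = sum_{j!=k} w_ij w_jk w_ki / sum_{j!=k} w_ij w_ki, 0 when the
  denominator is 0; C_w is the node mean. Reduces to the binary
  clustering coefficient on 0/1 graphs.
- **Characteristic path length L_w**: shortest-path mean with edge
  distance 1/w (infinity where w = 0), over all ordered pairs with finite
  distance; disconnected pairs are excluded with a warning (PLI matrices
  are in practice complete).
- **gamma, lambda**: C_w and L_w divided by their means over surrogate
  networks obtained by uniformly permuting the upper-triangle weights
  (symmetry restored). 50 surrogates by default, seed-deterministic. The
  surrogate preserves the weight distribution while destroying topology;
  a weight-shuffled input therefore normalizes to 1 in expectation.
- **kappa_w (weighted degree divergence)**: sum(s_i^2)/sum(s_i) of node
  strengths s_i = sum_j w_ij — the second moment of the strength
  distribution over its first; equals the common strength on
  strength-regular graphs and is >= the mean strength (Cauchy-Schwarz).
- **Modularity Q**: weighted Newman modularity of the best partition found
  by seeded Louvain optimization (networkx); tests verify Q never exceeds
  the exhaustive-partition optimum and attains it on structured cases.
- **MST**: maximum-weight spanning tree (maximum synchronization) by
  Kruskal on descending weight with lexicographic tie-breaking, which
  makes the tree deterministic under ties and invariant to positive
  weight scaling. Metrics are hop-count based and normalized into [0, 1]:
  leaf fraction L/M (M = N-1), diameter and mean eccentricity divided by
  M, and maximum betweenness centrality divided by (N-1)(N-2)/2 so a star
  center scores exactly 1.

The nine measures are computed per epoch and averaged by default; a
config switch (`metric_mode="aggregate"`) computes them once on the
epoch-averaged matrix instead. Mean PLI is identical under both modes
(linearity); the nonlinear measures differ slightly, and outputs are
labeled with the mode used. Exact numeric parity with any particular
legacy implementation of kappa_w or the gamma/lambda normalization is not
claimed; the chosen forms are documented above and their magnitudes on
21-channel data match published values.

## Statistics

- **Group differences**: two-sided Wilcoxon rank-sum per measure,
  collapsed across bands by per-subject mean (pooling bands as separate
  observations is available behind a flag). Exact enumeration when both
  groups have <= 10 tie-free values, otherwise the normal approximation
  with tie and continuity corrections.
- **Brain-behavior**: Spearman correlation (Pearson on average ranks,
  t-approximation p) between each measure x band and each of age, disease
  duration, MoCA, MDS-UPDRS III, ASRS-3, WAB-AQ — a 27 x 6 grid on the
  default three bands.
- Missing values: pairwise deletion per comparison; n_used is always
  reported. Significance is p < 0.05 strict, two-sided, with no
  multiplicity correction by default (Benjamini-Hochberg behind a flag) —
  matching the exploratory small-cohort design the pipeline reproduces.

## Synthetic data

**Signal model.** A phase-mixture oscillator rather than full Kuramoto
dynamics, because it gives analytically controllable PLI targets. Every
channel is a unit sinusoid at the band center whose phase is either an
independent random walk around the carrier (step SD 0.1 rad/sample,
enough to decorrelate the *pooled-sign* statistic across epochs) or a
copy of its driver channel's phase plus a fixed lag. The tracking state
is drawn per 1-second block with probability equal to the coupling
strength: blockwise rather than per-sample switching is essential,
because a 2-Hz-wide zero-phase filter averages over ~0.5 s and would
erase a sample-wise mixture. White noise (SD 0.2 uV) and 1/f background
(weight 0.1, spectrally shaped white noise) are added. Lags default to
pi/4 — away from the PLI blind spots at 0 and pi — and can be a per-pair
matrix; the cohort generator draws distinct per-channel lags in
(pi/6, pi/2) so that two channels tracking a common driver still hold a
nonzero mutual lag (with a single common lag they would be zero-lag
synchronous and mutually invisible to PLI).

**Cohorts.** Default design mirrors the study: 15 + 7 subjects. A fixed
hub-dominated coupling template (channel 0 strongly coupled to all,
uniform(0.75, 1); other pairs uniform(0.3, 0.7)) is scaled per subject by
a Gaussian coupling scale, agPPA shifted +0.05/2 and PPAOS -0.05/2. The
hub structure spreads coupled time over every channel pair instead of a
20-edge spanning tree, which is what makes subject-level mean PLI
identifiable from 8 epochs. The scale defaults to 0.6 +/- 0.15: the
estimator's response to weak coupling is non-monotone below a scale of
about 0.35 (partial tracking first destroys the sign-autocorrelation
bias of uncoupled pairs before genuine locking dominates), so the cohort
operates on the monotone rising branch, with a between-subject spread
that dominates the estimator's sampling noise at 8 x 1024 samples.

**Planted associations.** A behavioral score is
intercept + slope x (true measure) + Gaussian noise, where the true
measure is computed on the subject's coupling matrix itself. When a
target Spearman rho is requested, the noise SD is calibrated from the
realized spread of the true measure via the bivariate-Gaussian identity
rho = (6/pi) asin(r/2). Scores not carrying an effect are drawn around
group-typical medians and clipped to their valid ranges. Recordings are
whole seconds long (one epoch of headroom over the 8 required) so the
built-in EDF writer (1-s records, symmetric 16-bit quantization) accepts
them.

**What the simulator does not emulate**: volume conduction and reference
effects, genuine artifacts beyond amplitude spikes, nonstationary
vigilance drifts, spatially structured 1/f topographies, and any regional
physiology — passing tests demonstrate correctness of the estimators and
statistics under known ground truth, not clinical validity on real EEG.

## Problem sizes and numerical choices

The bundled study runs 22 subjects x 21 channels x 9 (8 + 1 spare)
epochs x 3 bands; recovery experiments use 100 replicate cohorts at
n = 22 and a single n = 100 cohort; brute-force oracle comparisons use
random graphs of 4-8 nodes (exhaustive partition and Pruefer-sequence
enumeration stay tractable there). Surrogate counts default to 50.
Degenerate inputs fail loudly: constant channels (undefined phase),
all-zero matrices (undefined kappa_w/modularity), disconnected graphs
(MST), fewer clean epochs than requested. Weight ties in the MST are
broken lexicographically; Louvain and surrogate draws are
seed-deterministic; same-seed simulations are bit-identical.

## Known limitations

- PLI magnitudes at 8 x 1024 samples carry the positive small-sample
  floor described above; between-condition *contrasts* and rank-based
  associations are meaningful, absolute PLI levels are not.
- The per-epoch vs aggregated choice for graph measures is not settled in
  the field; both are implemented, per-epoch is the default and outputs
  say which was used.
- No regional/nodal reporting, no alternative connectivity estimators
  (wPLI, coherence, synchronization likelihood), no regression modeling
  with covariates; the statistics deliberately stop at the exploratory
  rank-based design they reproduce.
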