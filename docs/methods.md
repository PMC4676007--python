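# Methods

This note documents the models, conventions and numerical choices behind
`tcsync`, and what the synthetic-data tests do and do not demonstrate.

## Signal model and conventions

All times are seconds (64-bit floats) with t = 0 at recording start; every
epoch and window is half-open `[start, end)`, so an event exactly at `end`
belongs to the next interval. LFPs are microvolts at a fixed sampling rate
(analysis rate 500 Hz; higher acquisition rates are decimated with
polyphase FIR anti-aliasing, integer factors only).

Band-limiting uses an order-4 Butterworth band-pass (default 1–120 Hz)
applied forward–backward (`sosfiltfilt`), so the filter's phase response
cancels and downstream instantaneous-phase estimates are undistorted. The
1–120 Hz default is the analysis band; the wider acquisition-hardware band
(1–180 Hz) is deliberately not used for analysis.

Rest sessions drop their first and last minute before analysis (a 10-min
session yields an 8-min epoch); sessions with the neuromodulation protocol
are analyzed as whole tracks. Stimulation sessions are analyzed in the
500 ms following each pulse onset; the two epochs of a couplet overlap
whenever the intra-couplet delay (uniform 150–250 ms) is under 500 ms, and
both are kept and flagged rather than merged.

## Phase and PLV

Instantaneous phase is the argument of the FFT-based analytic signal,
wrapped to (−π, π]. Phase is computed once per analysis epoch and then
sliced into windows; recomputing per window would put Hilbert end artifacts
into every window. The first and last 5% of each epoch's samples are
excluded from windowing for the same reason. Segments must be ≥ 64 samples
and non-constant; PLV needs ≥ 25 samples (50 ms at 500 Hz).

`PLV = |mean exp(i(φx − φy))|` is computed for all channel pairs at once as
`|Z Zᴴ|/T` with `Z = exp(iφ)`; the upper triangle is mirrored so the matrix
is bit-exactly symmetric, and the diagonal is exactly 1. PLV is computed
between electrodes (LFP channels), not sorted units.

## Graphs

Each window's PLV matrix is binarized at the 75th percentile of *that
matrix's* upper-triangle weights; edges are kept when strictly greater than
the threshold, so an all-tied matrix yields an explicitly flagged empty
graph instead of an arbitrary edge subset. Percentiles use the (n+1)p
order-statistic interpolation (the 75th percentile of {0.1 … 0.6} is
0.525). Percentile 0 is special-cased to threshold 0, keeping every
positive-weight pair. A pooled-threshold mode (session-level weight
distribution) is not the default; per-matrix thresholding pins per-window
density near 25%, which is the convention all shipped statistics assume.

Admissibility follows two rules: a graph is kept only if ≥ 99% of its nodes
lie in the largest connected component (for n ≤ 100 this means all nodes),
and ensembles of ≥ 20 graphs additionally drop graphs outside the 5th–95th
percentile of the ensemble's node-count, edge-count or density
distributions. Every removal is counted per criterion in the run manifest;
nothing is silently dropped.

Clustering uses the binary-undirected convention `Cᵢ = 2tᵢ/(kᵢ(kᵢ−1))` with
`Cᵢ = 0` for degree < 2, averaged over **all** nodes. The characteristic
path length averages breadth-first shortest-path lengths over ordered pairs
of distinct nodes, excluding infinite (disconnected) distances from the
mean and reporting their count; a harmonic-mean mode is available.
Betweenness is Brandes' algorithm normalized by (n−1)(n−2)/2. The graph
algorithms are delegated to networkx and are verified exactly against
independent brute-force oracles (triangle enumeration, Floyd–Warshall,
exhaustive geodesic enumeration) in the test suite.

## Spike analysis

Units are screened on the analysis epoch: mean rate strictly below 4 or
strictly above 100 spikes/s rejects the unit (`rejected_rate`; exactly 4 or
100 is kept), and more than 1.5% of inter-spike intervals below 2 ms
rejects it as an implausible-ISI unit (`rejected_isi`). The ISI rule is an
operationalization of "implausible inter-spike-interval distribution" — a
standard sorting-quality heuristic, with both thresholds configurable and
the criterion flagged as such in reports. Binning is 1 ms; two spikes in
one bin collapse to a single 1 with a logged warning. Evoked rates pool
spikes over all 500-ms post-stimulus epochs (equal-length epochs make
pooling identical to averaging per-epoch rates).

## Statistics

All contrasts are two-sided Wilcoxon rank-sum tests. For pooled n ≤ 12 the
p-value is exact by enumeration of all rank assignments (midranks for
ties; two-sidedness via the symmetry of the rank-sum statistic around its
null mean). Larger samples use the tie- and continuity-corrected normal
approximation. At the crossover (pooled n = 12) the two branches agree to
within ~0.02 in p; the continuity correction is kept because it is the
closer of the two approximations and immaterial at the pipeline's sample
sizes. Bonferroni correction multiplies by the number of contrasts in the
declared family (clamped at 1); the default grid groups each simultaneous
set of contrasts (e.g. the four REAC firing-rate contrasts) into one
family.

The sampling unit is declared explicitly per measure: firing rate — unit ×
window; PLV — channel-pair × window; C and L — one graph per window. When
two discrete samples have equal medians, the reported direction falls back
to the sign of the mean-rank difference (the test's own direction
estimate); whenever the median difference is nonzero it determines the
sign.

## Synthetic-data generator

LFP sources are stochastic Kuramoto oscillators, one per electrode of two
3×3 matrices (VPL and S1), integrated by Euler–Maruyama at dt = 1/fs (2 ms
at 500 Hz; the phase dynamics are slow relative to this step):

    dφᵢ = ωᵢ dt + Σⱼ Kᵢⱼ sin(φⱼ − φᵢ) dt + σ dWᵢ

with cosine readout `x = A cos(φ) + ε`, `ε ~ N(0, obs_noise²)`. PLV is
exactly the statistic this model parameterizes, which makes parameter
recovery through the full analysis chain a well-posed test.

Defaults, with units and rationale:

| parameter | default | why |
|---|---|---|
| natural frequencies | U(10, 14) Hz | one analyzed rhythm band; pairwise detuning (≤ 25 rad/s) comparable to the summed coupling, keeping PLV in its sensitive mid-range (~0.84 at rest). A wide draw such as U(8, 30) Hz makes detuning dwarf any plausible coupling: PLV saturates low, coupling multipliers become undetectable, and outlier-frequency channels are isolated in nearly every thresholded graph |
| coupling | 2.0 rad/s within region, 1.0 between | block structure with partial global synchrony |
| phase noise σ | 2.5 rad/√s | window-to-window PLV variability without destroying locking |
| amplitude / obs. noise | 50 µV / 10 µV | SNR 5, typical for LFP matrices |
| base rates | U(8, 30) spikes/s | inside the 4–100 spikes/s acceptance band |
| refractory | 2 ms, deletion after thinning | matches the 1-ms-bin no-collision property and realistic ISIs |
| evoked gains | ×1.5 rate, preset-specific coupling, during [onset, onset + 500 ms) | multiplicative boosts mirror the evoked-epoch definition |

Spikes are inhomogeneous Poisson by thinning (rejected when max rate ×
refractory ≥ 1). The stimulus schedule places first pulses every 500 ms
and second pulses a uniform 150–250 ms later (5-ms pulse width as
metadata). One master seed spawns independent named sub-streams
(parameters, phase noise, observation noise, spikes, schedule), so a
config + seed reproduces a recording bit-exactly and partial re-runs keep
streams independent.

Group × condition effects are multiplicative presets (shipped as versioned
YAML): chronic-pain (CCI) rest coupling 1.5× control (CR); tactile
stimulation boosts evoked-epoch coupling (1.4× its session baseline); the
REAC protocol multiplies rates by 1.43 / 1.93 / 1.09 / 1.41 (CR-rest /
CCI-rest / CR-tactile / CCI-tactile) and coupling by 1.3×. The rate
multipliers are observed effect sizes; the synchrony multipliers are
calibration choices constrained only in direction. REAC sessions are
simulated as 15-min epochs with the modulation active throughout (the
device's 1.5-s impulse cadence is represented only as condition metadata).

In the full pipeline, oscillator frequencies and unit base rates are drawn
once per *group* and shared across that group's four conditions: the
conditions are recorded from the same animals and electrodes, so the same
units recur. Independent redraws per condition would bury small injected
rate effects (e.g. the 1.09× multiplier) under unit-sampling noise with
only 18 units.

### What the generator does not emulate

No 1/f spectra, volume conduction, conductance-based biophysics, spike–LFP
coupling, anesthesia-depth dynamics or behaving-animal nonstationarity.
Passing tests therefore show that the *analysis chain* is correct and
sensitive to the effects the generator injects — not that real recordings
would show those effects. Two consequences worth knowing: realized REAC
percent-changes come out a few percent below the injected multipliers
(the 2-ms refractory compresses high rates disproportionately), and with
per-matrix thresholding only ~10–20% of windows yield fully connected
(admissible) graphs, so the graph-statistics tables rest on the retained
subset — the manifest reports exactly how many graphs each criterion
removed.

## Problem sizes

Default sessions are 600 s (rest, tactile; rest trimmed to 480 s) and
900 s (REAC) at 500 Hz with 18 channels — a full 8-cell run takes a few
minutes on one CPU. The shipped acceptance script runs the same pipeline
at 300-s sessions, and calibrates the identical-preset null on 120-s,
10-channel sessions over 10 seeds; all sizes appear in its JSON output.

## Known limitations

- Rank-sum p-values for PLV, C and L treat window-level samples as
  exchangeable, as the comparison design specifies; windows are serially
  dependent, so those p-values are calibrated only under that assumption
  (the firing-rate null, where samples are exchangeable, is calibrated
  explicitly).
- The N of each test conflates units/pairs/windows; the sampling unit is
  reported per measure rather than modeled hierarchically (no
  animal-level random effects).
- Betweenness centrality is computed and exported but has no downstream
  consumer in the comparison grid.
- The ISI-plausibility rule stands in for a spike-sorting quality judgment
  the pipeline cannot make from timestamps alone.
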