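# Methods

This note documents the models, conventions and numerical choices behind
`chronomap`, and what the synthetic validation does and does not show.

## Stimulus designs

Two paradigms are generated by `chronomap.design`.

**Event-related duration discrimination.**  Sixteen trials per run, one
per combination of four first-stimulus (S1) durations {0.2, 0.4, 0.6,
1.0 s} and four grating orientations.  Each trial: S1, an interstimulus
interval drawn uniformly from {4.00, 4.08, …, 5.20 s}, a comparison
stimulus S2 of duration S1 × (1 ± 0.4) (sign randomized), and a 2-s
response cue.  Runs are sampled at 1.368 s (one volume per acquisition),
169 volumes per run.  The paradigm does not pin down the spacing between
trials beyond the interstimulus interval, so the builder uses a 2-s
lead-in and an inter-trial interval uniform on {3.00 … 4.48 s} in 0.08-s
steps — chosen so that even the worst-case draw fits inside the 231.2-s
run with a rest tail, as event-related sessions typically end.

**Cyclic design for pRF mapping.**  Ten duration pairs (standard T,
comparison 1.5 T), T = 0.2 … 2.0 s in 0.2-s steps, presented once per
44-s cycle in ascending or descending order.  S1 and S2 are back to back,
followed by a 1.37-s vertical-orientation interval per trial and a 2.03-s
vertical interval between cycles.  The nominal cycle content sums to
43.23 s; the builder pads each cycle tail with vertical orientation to
exactly 44 s, preserving the 22-volume cycle at TR = 2 s.  Standard-first
versus comparison-first order is assigned by a row/column-permuted
checkerboard: exactly five standard-first trials per cycle *and* both
orders for every pair across cycles, so any run with an even number of
cycles exposes all 17 unique S1 durations (standards ∪ comparisons:
0.2, 0.3, 0.4, 0.6, 0.8, 0.9, 1, 1.2, 1.4, 1.5, 1.6, 1.8, 2, 2.1, 2.4,
2.7, 3 s).

Event times are continuous seconds; mapping to volumes happens downstream
as `floor(t / TR)`, 0-based.

## Generative model

`simulate_bold` mirrors the assumptions of the analyses exactly: per voxel
*v*, each stimulus offset with presented duration *d* contributes a neural
impulse of height

    amplitude_v · exp(−(d − μ*_v)² / (2 σ*_v²))

at the volume containing the offset; the impulse train is convolved with
the canonical HRF on the TR grid and added to a constant baseline, a
single sinusoid drift (period ≥ 120 s, so the high-pass stage can remove
it; random phase per voxel), and i.i.d. Gaussian noise.  Impulses sit at
stimulus *offsets*, not boxcars over the stimulus, because offset is the
moment duration information becomes available and it is the convention
used by both analysis routes; sharing the convention makes noise-free
recovery exact, which the self-consistency checks exploit.

Second-stimulus responses are a generator flag (default on, gain 0.5,
same tuning): they contaminate S1-locked analyses the way a real session
would, and the label-recovery checks keep them on.  The pRF recovery
checks turn them off, because "noise-free recovery with R² ≈ 1" is only a
meaningful statement when the generated signal lies inside the model
family being fitted.

Truth maps default to a 20 × 20 × 4 voxel lattice (≈1,600 voxels keeps
every stage under a minute), voxel size 2 mm, preferred durations varying
linearly along axis 0 between the experiment's duration range endpoints;
`shuffled` permutes μ* across voxels, destroying the topography while
preserving its distribution — the null used to calibrate the slope test.
Tuning spread σ* defaults to 0.3 s (0.15 s in the four-duration labeling
checks, where clusters must be separable; 0.5 s in the 17-duration pRF
checks, matching the broader sampled range), amplitude 1 on baseline 100
(≈1% signal change), white noise SD 0.5 and drift amplitude 0.5 on that
baseline — a deliberately clean regime: the generator makes no attempt at
physiological noise, autocorrelation, motion, or anatomical variability,
so passing tests demonstrate correctness of the estimators, not robustness
to real fMRI artifacts.

The behavioral model draws a correct response with probability
Φ(sensitivity · |ΔT| / T) — chance at zero sensitivity, perfect in the
limit — and computes per-condition coefficients of variation from
perceived durations with scalar-timing noise SD = T / (1 + sensitivity).

## GLM route

One regressor per S1 duration (impulse at offset), one at S2 onsets, one
at response-cue onsets, all convolved with the canonical double-gamma HRF
(peak 6 s, undershoot 16 s, ratio 6:1, 32-s support, unit peak).  The
high-pass filter is implemented as a discrete-cosine drift basis
(`K = floor(2 · run_length · 0.0083) + 1` components including the
constant) entered as regressors rather than applied as pre-filtering, so
degrees of freedom stay explicit.  Runs concatenate block-diagonally —
per-run task, drift and intercept columns — and the per-duration contrast
averages the corresponding betas across runs.  OLS is vectorized over
voxels via the pseudoinverse; t = c'β̂ / √(σ̂² c'(X'X)⁻¹c) with
df = T − rank(X).  Rank-deficient designs are rejected naming the
collinear columns.

Winner-take-all: a voxel is labeled with the duration of its largest
t-value if that value exceeds 3.13 (the single-subject threshold); exact
ties resolve to the shorter duration, deterministically.  An optional
minimum-cluster-size filter (face connectivity) stands in for the original
random-field cluster correction, which is out of scope; the default is no
filtering.

## Duration pRF route

The stimulus profile is an n_volumes × n_durations indicator marking which
S1 duration (standard or comparison alike) had its offset in which volume.
The predicted neural series for parameters (μ, σ) is the profile times
Gaussian weights exp(−(d_b − μ)²/(2σ²)) — a Gaussian over linearly spaced
duration evaluated at the presented bins, no sub-bin integration — then
HRF-convolved per run (convolution never crosses run boundaries) and fit
to the voxel series by linear regression with intercept.

Fitting is coarse-to-fine: exhaustive search over μ ∈ presented durations
× σ ∈ {0.05, 0.10, …, 1.0 s} (fitted spreads in this paradigm stay below
1 s), followed by Nelder-Mead refinement from the grid optimum with the
simplex tolerance set to 10⁻³ (the optimizer runs at a 10× tighter xatol
so the returned parameters are accurate at the nominal tolerance); σ is
clipped to the grid range.  The amplitude β is constrained non-negative —
a tuned response is a positive deflection — so parameter sets whose best
linear fit is anticorrelated score R² = 0.  The refined optimum is only
accepted if it does not degrade the grid optimum, so refinement never
lowers R².  Voxels with R² ≤ 0.1 are excluded from all further analyses;
constant series return an excluded result rather than an error.  Label
maps carry μ̂ snapped to the nearest presented duration, with R² as the
statistic.

## Topography quantification

All metrics operate on a `LabelMap` (per-voxel duration or NaN) plus a
planar border geometry: a progression axis, a reference border D1
(posterior, by this package's convention), an opposite border D2, and
TD = |D2 − D1|.  The original surface flattening and hand-drawn borders
are out of scope; the synthetic lattice makes planar borders exact.

* **wRD** = Σᵢ wᵢ·RDᵢ / Nvd with wᵢ = Nnbrsᵢ/Nvd and RDᵢ = D1ᵢ/TD.
  Adjacency is face adjacency (4 neighbors on a 2-D sheet, 6 in 3-D) with
  the voxel itself excluded — the simplest convention, exposed as
  parameters since the formula's source leaves the neighborhood
  definition open.  Note the weight construction double-normalizes by
  Nvd; the implementation follows the printed formula literally, and the
  brute-force oracle in the tests confirms the arithmetic.
* **Slopes** regress wRD on duration rank 1…k (matching equally spaced
  plotting); a per-second slope is also reported, and an optional split at
  1 s yields separate sub-/supra-second slopes.  The across-subject test
  is a one-sample Wilcoxon signed-rank of the slopes against zero,
  one-sided (negative), exact null enumeration for n ≤ 15, zeros dropped
  and counted.  A one-sample test is used even where the source text says
  "rank sum", since the hypothesis is one-sample.
* **Preferred-duration profiles** bin voxels into 1.5-mm planes along the
  axis; each plane's preferred duration is the majority label (ties to
  the shorter duration), positioned at bin-center D1/TD; subjects' (RD,
  PD) pairs are pooled, sorted, and reduced by averaging every five
  consecutive values (a trailing shorter group is averaged as is).
* **Weighted centroids** weight each voxel's position by its integer
  same-label neighbor count; an all-isolated cluster falls back to the
  plain mean and is flagged.
* **Map comparison** reports per-label centroid distances from each map's
  reference border, the two extents (TD), per-label overlap
  |same label in both| / |that label in either| (maps must share a
  lattice), and cluster-size proportions.
* **Behavior correlation**: Kendall τ-b between per-subject slopes and
  accuracy / coefficient of variation; constant inputs are flagged rather
  than given a τ.

## Tuning analysis

Cluster normalization follows, per voxel and run, (x(t) − MB)/MB with MB
the voxel's grand-mean signal across runs (a per-timepoint mean across
runs is available behind a flag, since the verbal definition is
ambiguous); traces are averaged over voxels, then runs, and divided by the
SD of the voxel-averaged trace — the output has unit SD by construction,
and zero baselines or zero-variance traces raise.  Responses are single
samples two volumes after each S1 offset (no averaging window), averaged
within condition.  Profiles are normalized to the preferred-duration
response for the four-duration design (so the profile is exactly 1 at PD)
or left on the normalized scale for the 17-duration design, where
durations are first grouped onto the ten trial-type pairs (durations
occurring in two pairs — 0.6, 1.2, 1.8 s — contribute to both, weighted by
occurrence count).  PD ± k is defined on the condition rank scale,
truncated at the ends.  Signed-rank tests compare PD against the mean of
available PD±1 and PD±2 responses per cluster (one-sided, PD greater), or
the near-union (PD ∪ PD±1) against PD±2.  Cyclic runs can be collapsed to
a mean 22-volume cycle waveform, with descending-run cycles time-reversed
before averaging.

## Venous-artifact checks

GLM route: flag voxels with z above a threshold (default 8) *and* mean
intensity strictly below a low quantile (default 5%) of in-mask intensity.
pRF route: flag included voxels with σ ≥ 1 s, and report the Kendall
correlation between σ and μ (a systematic relationship would suggest the
spread is tracking something other than tuning).  The thresholds are
parameters: the original diagnostics were visual scatterplots with no
numeric cutoffs, so the defaults encode "very high z", "very low
intensity" and "all genuine σ < 1 s" conservatively.

## Validation studies and problem sizes

`chronomap.pipeline` bundles the recurring studies: noise-free
winner-take-all label recovery on a full 18-run session (fraction of
suprathreshold voxels labeled with the duration nearest their planted
μ*); pRF parameter recovery over 300 voxels through one ascending and one
descending cyclic run, noise-free and at a white-noise level calibrated by
bisection so pilot fits reach mean R² ≈ 0.3; and replicate cohorts of 10
subjects — each a 12 × 12 lattice pushed through two simulated runs and
the GLM route — whose wRD slopes feed the signed-rank test, with planted
gradients measuring detection and shuffled gradients measuring the false
rejection rate.  The cohort subjects are deliberately small so that 100
replicate cohorts complete in about a minute; detection is limited by the
consistency of the slope sign, not by per-subject map quality, so small
lattices suffice.

## Known limitations

The synthetic noise model (white + one sinusoid) is far cleaner than real
fMRI noise; thresholds tuned here (t > 3.13, R² > 0.1) inherit their
operating characteristics from the original acquisition context, not from
these simulations.  Borders are planar and known exactly, sidestepping the
surface reconstruction, flattening and manual border placement that
dominate uncertainty in real data.  Group-level inference (second-level
ANOVA, random-field correction, template morphing) is out of scope; all
analyses operate on per-subject lattices.
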