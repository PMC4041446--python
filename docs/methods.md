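# Methods

`tatabend` analyses single-molecule FRET measurements of promoter-DNA
bending by the basal transcription factors TBP and TFB/TF(II)B, and ships a
synthetic-data generator that emulates both experiment geometries so the
whole chain is testable without laboratory data. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic data do and do not capture.

## Conformational model

DNA bending is modelled as a continuous-time Markov chain over discrete
conformational states, each with its own proximity ratio (uncorrected FRET
efficiency) E:

* **two-state** (archaeal TBPs): unbent ⇄ bent, e.g. E = 0.25 / 0.49 for
  the SSV promoter;
* **linear three-state** (eukaryotic TBP/TF(II)B): unbent ⇄ intermediate ⇄
  fully bent (E = 0.32 / 0.60 / 0.75 for the H2B promoter), with direct
  unbent ⇄ fully-bent steps forbidden by construction.

Dwell times in each state are exponential with the configured means; for
the middle state of the linear chain the exit splits between its two
neighbours with a configurable branching probability (default 0.5). Paths
are started from the analytic stationary occupancy so that finite windows
are unbiased equilibrium samples.

## Synthetic data

**Camera (TIRF) traces.** Each frame integrates the state path over the
frame period: the emitted E is the dwell-time-weighted average of the state
E values, which produces the intermediate-valued boundary frames a real
camera produces and the idealizer must tolerate. The acceptor channel picks
up donor leakage `l·I_D` and direct excitation `d·I_total` when configured.
Noise is additive Gaussian per channel; because study conditions are often
quoted as a standard deviation of E(t), the configuration accepts either a
counts-level `noise_sd` or an `e_noise_sd`, the latter converted per frame
through sd(E) ≈ σ·sqrt((1−E)² + E²)/N for total intensity N. Photobleaching
is a single exponential-time step per fluorophore, drawn independently for
donor and acceptor: after an acceptor bleach the acceptor falls to
background and the donor rises to the full intensity; after a donor bleach
both channels fall.

**Confocal ALEX photon streams.** Diffusion bursts are phenomenological
envelopes: lognormal duration (median 1 ms, log-sd 0.5) and lognormal mean
rate (median 50 photons/ms, log-sd 0.3), both configurable. These envelope
statistics are conventions — typical for diffusing single molecules, not
measured here — and downstream results depend only on per-burst count
ratios, not envelope shape. Each burst is one molecule in one
conformational state drawn from the stationary occupancy (transit times are
far shorter than the dwell times of interest). Excitation alternates with a
100 µs period, 50/50 duty cycle; photons are generated by thinning so that
donor-excitation photons fall in the first half-period and
acceptor-excitation photons in the second, with the stoichiometry S setting
the rate split (dual-labelled S = 0.5, donor-only S = 1, acceptor-only
S = 0). Within the donor-excitation slot a photon is an acceptor photon
with probability E + l(1−E) + d. Background is Poisson per detection class
(defaults 400/300/300/0 photons/s for DD/AD/AA/DA, a realistic ~1 kHz
total). Timestamps are strictly increasing integer microseconds; collisions
are resolved by minimal forward shifts that conserve photon counts.

**Titrations and survival series.** Bent fractions are binomial samples of
the pseudo-first-order Langmuir isotherm f = c/(c+Kd) (protein in large
excess over the ~10 pM DNA), and complex survival is binomial sampling of
exp(−t/τ). Passing `None` for the sample size gives the noiseless curves.

What the generator does **not** emulate: optical point-spread functions and
3-D diffusion (bursts are envelopes), detector afterpulsing and dead time,
spectral fluctuations of the dyes, camera nonlinearity/EM gain statistics,
and any temperature model (temperature series are produced by running the
generator at per-condition dwell parameters). Passing tests therefore
demonstrate correctness of the analysis chain under the stated statistical
model, not robustness to every artifact of real data.

## Burst analysis

Burst search uses the sliding-window criterion on all photons pooled: a
photon qualifies when at least M photons fall within a window of length T
centred on it, and a burst is a maximal run of at least N consecutive
qualifying photons (defaults T = 500 µs, M = 30, N = 120; the
lower-brightness dye pair uses M = 10, N = 50). The centred window is the
package's convention — the criterion family is ambiguous about anchoring —
and a start-anchored mode is available behind a flag. The implementation is
O(n log n) via sorted searches and is property-tested against a brute-force
O(n²) oracle.

Counts per class are background-corrected by the class rate times the
burst duration (floored at zero). Background rates default to the
generator's ground truth when analysing synthetic streams; for external
data the class-wise mean rate outside burst regions is the recommended
estimate. Leakage/direct-excitation subtraction of burst counts is
supported but off by default; proximity ratios are reported uncorrected, as
is standard when absolute distances are not claimed. Then

    E = F_AD / (F_AD + F_DD),   S = (F_AD + F_DD) / (F_AD + F_DD + F_AA)

from summed counts per burst (not per-photon averages). Zero denominators
yield NaN and flag the burst.

**Kernel-density filtering.** Bursts are scored with two
exponential-kernel (time constant 100 µs, configurable) density statistics.
FRET-2CDE = 110 − 100·[(E)_D + (1−E)_A], where (E)_D averages, over
donor-excitation donor photons, the AD-photon density against the
self-excluded DD density (and symmetrically for (1−E)_A); a burst with
static FRET scores near 10, and within-burst E dynamics (acceptor
blinking/bleaching) push it out of the [8, 12] band. ALEX-2CDE =
|100 − 50·(BR_DexAex + BR_AexDex)| with BR the opposite-stream/own-stream
density ratio normalised by the opposite stream's size: near zero for a
dual-labelled molecule of constant, balanced brightness, large for
donor-only / acceptor-only bursts and for excitation-stream intensity
dynamics. The default selection keeps ALEX-2CDE ≤ 12; the FRET-2CDE band is
optional, mirroring its "if necessary" role. Absolute scores of kernel
statistics depend on formulation details; thresholds, not absolute values,
carry the scientific content here, and both scores are verified against a
naive loop-based oracle and for their threshold behaviour on labelled
simulations (30% donor-only contamination falls below 5% after filtering).

E histograms (bin width 0.025 on [−0.1, 1.1]) are fitted with sums of 1-3
Gaussians by least squares on bin counts, initialised at evenly spaced
percentiles. Weights are normalised component areas; the *bent fraction*
is the weight of the highest-mean component.

## Trace idealization

The idealizer is a K-state hidden Markov model with Gaussian emissions on
the one-dimensional E(t) series (matching the HaMMy-style convention), K
fixed by the user (2 archaeal, 3 eukaryotic) — no model selection. Fitting
is plain maximum-likelihood EM (Baum–Welch) over all traces pooled, with
scaled forward–backward vectorized across traces. Frames with undefined E
are missing emissions (likelihood 1), bridged by the transition model,
never zeros. The log-likelihood is asserted non-decreasing at every
iteration. Initialization: state means at evenly spaced percentiles of the
pooled E values; nine further restarts draw means uniformly between the 1st
and 99th percentiles (seeded), and the best final likelihood wins — the
random restarts matter when a state is rarely occupied and the percentile
init collapses onto the majority state. Emission sds are floored at 1e-3 so
noiseless data converge to the floor instead of a singular likelihood.
States are relabelled in ascending order of mean, making decoded partitions
invariant to initialization labelling. Decoding is Viterbi, deterministic,
with ties broken toward the lower-index (lower-E) state; it is tested
against exhaustive path enumeration on short traces.

Bleach truncation: the analysable range ends at the first sustained drop
of I_D + I_A below half its preceding running median (5-frame windows), or
at an anticorrelated acceptor loss (acceptor falls below half while the
donor rises above 1.5× its own median).

Dwells are run-length encodings of the decoded path, in seconds. The first
and last dwell of every trace are censored (entry/exit unobserved) and
excluded from fitting by default.

## Kinetics

Mean dwell times come from mono-exponential fits, in two modes because the
field uses both: **MLE** (τ = sample mean, SE = τ/√n) and **histogram**
least squares of A·exp(−t/τ) with bin width two frame periods and the first
bin dropped. Both modes carry a *missed-event guard* for camera-sampled
dwells: transitions faster than about two frames are unresolvable, so
dwells shorter than two frame periods are unreliable. The histogram mode
drops the first bin; the MLE mode optionally left-truncates at the same
2-frame limit and uses the truncated-exponential maximum-likelihood
estimate τ = mean(d | d ≥ c) − c, exact under memorylessness. On simulated
two-state dynamics (0.18 s bent dwell at 50 Hz, E-noise 0.07) the plain
mean overestimates τ by ≈20% purely through missed short dwells, while the
guarded estimate is within a few percent; the guard threshold is the fixed
2-frame resolution limit, not a tuned quantity.

Transition rates under a declared topology use the count-based branching
estimator k_ij = (n_ij/Σ_j n_ij)/τ_i, which reduces to k = 1/τ for
single-exit states and satisfies Σ_j k_ij·τ_i = 1 by construction.
Transitions forbidden by the topology (direct unbent ⇄ fully-bent) above a
5% count share raise a warning — at adequate frame rates they are
resolution artifacts. Reported rates are rounded to one decimal and
temperature factors to the nearest integer, matching how the field prints
them; full precision is retained on the fit objects.

Binding isotherms are fitted as f = c/(c + Kd) by weighted least squares
(binomial standard errors when the per-point sample size is known),
assuming free ≈ total protein. Survival series are fitted as exp(−t/τ)
with the amplitude fixed at 1 by default (f(0) = 1), optionally free.

## Problem sizes and numerical settings

Parameter-recovery checks run at desk scale: 150–300 traces of 30–60 s for
dwell recovery, 100–200 traces for three-state mean recovery, 6,000–10,000
simulated bursts for population recovery, 500 molecules × 40 time points
for survival, 8 log-spaced concentrations × 1,000 molecules for titration.
EM uses a relative log-likelihood tolerance of 1e-6 (max 100 iterations,
10 restarts); curve fits use scipy's Levenberg–Marquardt/TRF with
documented initial guesses. All randomness flows through seeded
`numpy.random.Generator` instances — identical seed and configuration give
bit-identical streams, traces and results.

## Known limitations

* Proximity ratios only: no gamma-factor or distance calibration, no
  time-resolved (TCSPC) analysis.
* The HMM assumes Gaussian, state-independent-width emission noise and
  per-frame independence; camera frame averaging at state boundaries is
  emulated by the generator but not modelled in the emission density.
* Dwell estimates inherit the camera's missed-event limit; the 2-frame
  guard corrects the mean under memorylessness but cannot recover dynamics
  faster than the frame time.
* The kernel-density filter implementation reproduces the documented
  threshold behaviour of the 2CDE family; absolute scores are not
  guaranteed to match other implementations digit for digit.
* Binding fits assume pseudo-first-order conditions; they are wrong when
  DNA and protein concentrations are comparable.
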