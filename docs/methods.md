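# Methods

`myovowel` implements a myoelectric vowel-synthesis chain — Bayesian EMG
filtering, drive-to-formant mapping, cascade formant synthesis,
intelligibility statistics — together with a virtual-subject /
virtual-listener simulator that stands in for human experiments. This
note records the models, the parameters that matter, the numerical
choices, and what the simulator does and does not establish.

## The drive filter

The observation model treats each 1-ms rectified-EMG sample as a
Poisson count of fiber depolarization events, `n ~ Poisson(gain · x)`,
with `x ∈ [0, 1]` the latent drive. The prior is a jump-diffusion,
`dx = α dW + (U − x) dN_β`, with `U ~ Uniform[0, 1]`: gradual drift
with rare resets at force onset/offset. The jump destination is a
uniform draw, taken literally; the alternative reading (a draw from the
current distribution of x) would make the jump term a no-op on the
density, which cannot be what a tracking filter needs.

The filter discretizes the density on `n_bins = 100` centers
`x_i = (i + 0.5)/100` and alternates, per sample:

1. **Propagation** — an explicit finite-difference diffusion step with
   coefficient `c = α²·dt / (2·Δx²)` and *reflecting* boundaries (drive
   cannot leave [0, 1]), then convex mixing toward the uniform density
   with weight `β·dt`. Construction conserves probability exactly; the
   step is rejected at build time if `c > 0.5` (explicit-scheme
   stability) or `β·dt ≥ 1`.
2. **Update** — pointwise multiplication by the Poisson likelihood of
   `n = round(gain · sample)`, computed in the log domain and shifted
   by its maximum before exponentiation. A posterior that underflows to
   all-zero resets to uniform with a warning.
3. **Readout** — the MAP bin center, ties broken toward lower drive
   (the conservative choice for a signal that gates sound); an optional
   quadratic sub-bin interpolation exists but is off by default so the
   output grid is predictable.

Defaults `α = 0.1 s^-1/2`, `β = 1 s^-1`, `gain = 50`, `dt = 1 ms`.
The continuous sample-to-count mapping and the grid are engineering
choices — there is no canonical discretization — and the defaults were
picked so the canonical step response behaves correctly: a 0 → 0.8
drive step is crossed at the 90% level within a few samples (median
well under the 100-ms bound the tests enforce), while the steady-state
output SD at constant drive stays below that of a 10-Hz low-pass
rectified envelope of the same stream. With α, β → 0 the filter
converges to the Poisson ML value n/gain, which the tests use as an
analytic anchor. Grid-resolution robustness is checked by running a
64-bin filter against a 1024-bin reference on identical streams; that
comparison uses α = 0.03, the largest default-order drift admissible
under the 1024-bin stability bound.

## Mapping and targets

The five-vowel target table (average adult-male F1/F2 plus the drive
levels each vowel requires under both transforms) ships as a CSV
fixture. The Cartesian boundary frequencies are not free parameters:
they are recovered by least squares through the (drive, formant) pairs
of the fixture, giving F1 ∈ [≈272, ≈971] Hz and F2 ∈ [≈702, ≈2806] Hz.
Fitting through the /i/ and /ɑ/ anchor rows alone reproduces every
fixture drive cell to two decimals (max residual ≤ 0.01), so the
reconstruction is used as an exactness check in the acceptance tests.

Polar defaults place the center at the box midpoint with
`K_F1 = −(F1hi − F1lo)/2` and `K_F2 = +(F2hi − F2lo)/2`, satisfying the
negative-F1 orientation at (e1, e2) = (1, 0). The fixture's own polar
drive columns are mutually inconsistent with any single (center, K)
pair at rounding precision, so they are shipped as documentation but
not used as an exactness target. Under these defaults /u/ requires
e1 ≈ 1.002 and is flagged unreachable; virtual polar sessions clip the
target magnitude to 1 and exclude the trial from visual-error
summaries. Drives outside [0, 1] are clipped before mapping (with a log
counter); whether the original device clipped or rescaled is unknown,
and clipping is the only choice that preserves the MVC interpretation.

Visual error is the Euclidean distance in Hz to the target, summarized
as the mean over the final 1 s of a 5-s trial; the performance measure
is p = 1/VE, so a relative VE change ΔVE implies a relative performance
change ΔVE/(1 + ΔVE). Plot/screen conventions follow the vowel chart
(F1 down, F2 left), putting the Cartesian rest position (0, 0) at the
top right.

## Synthesizer

A phase-accumulating impulse train (fractional periods carry, so a
120-Hz train at 16 kHz over 5 s yields 600 ± 1 pulses) excites a
cascade of digital two-pole resonators,
`y[k] = A·x[k] + B·y[k−1] + C·y[k−2]` with `r = exp(−π·bw/fs)`,
`B = 2r·cos(2πf/fs)`, `C = −r²`, `A = 1 − B − C` (unity DC gain, poles
strictly inside the unit circle for any in-range command). F1 and F2
coefficients update every audio sample from the linearly interpolated
1-kHz command trace — zero-order hold would add audible stair-step
transients. Defaults are Klatt-conventional: fs = 16 kHz, F0 = 120 Hz,
bandwidths 80/90 Hz, a fixed third resonance at 2900 Hz (bandwidth
150 Hz). Voicing is continuous (no volume channel); the clip is
peak-normalized to 0.9 afterwards. Each rendered trial opens with a
0.25-s rest segment at the formants of zero drive (duration
configurable; no reference value exists for the original device).

Formant fidelity is verified with a measurement instrument,
`spectral_peaks`: the Welch log-power spectrum smoothed with a Gaussian
wide enough (80 Hz) to erase the 120-Hz harmonic comb, peak-picked with
a 0.05 log10-power prominence floor to reject residual ripple in the
long valley between widely spaced formants. For every fixture vowel the
two recovered peaks fall within one bandwidth of the commanded values.

## Intelligibility statistics

Fraction correct is N_correct/N_total. Cohen's κ compares one listener
with the intended vowels via the confusion-matrix marginals; Fleiss's κ
measures agreement among listeners from the trial × category count
matrix (both delegated to `statsmodels.stats.inter_rater`, with
brute-force formula oracles in the tests). Landis–Koch bands are
half-open `[lo, hi)` with the top band closed at 1 — the published
banding (0–0.20, 0.21–0.40, …) leaves values like 0.205 unassigned, and
half-open intervals resolve that without moving any printed cutpoint.
The per-condition session report adds the mean and sample SD of κ
across listeners; Fleiss's κ is computed per condition (per session),
not pooled across transforms.

## The simulator

The virtual subject reaches from rest (0, 0) to each vowel's required
drive pair along a minimum-jerk profile (reach time 1 s, the natural
scale for a deliberate 5-s aiming movement), holds it, and is distorted
in order by: co-contraction cross-talk (a fraction c of each channel's
clean drive added to the other), signal-dependent noise (per-sample
Gaussian with SD = coefficient × drive, the standard motor-noise model),
and optional sinusoidal tremor with random phase; the result is clipped
to [0, 1]. The impairment parameterization is qualitative by design —
the study population's actual noise magnitudes are unknowable from
published group statistics — so the `cp` profile (signal-dependent
noise 0.3, co-contraction 0.2) is an exploratory operating point, not
an estimate of any patient.

EMG generation inverts the observation model (counts/gain at 1 kHz), so
filter-recovery tests are genuine closed loops. MVC normalization
implements the protocol rule: the maximum 250-ms sliding-window mean
across five 5-s attempts. Sessions are seeded permutations of the
5-per-vowel multiset; every stage draws from seeds spawned from one
root SeedSequence, making manifests, visual errors and WAV bytes
bit-reproducible.

The virtual listener takes the mean (F1, F2) over the final second,
adds isotropic Gaussian perceptual noise (default SD 50 Hz, roughly a
just-noticeable-difference scale for F1/F2; configurable, including a
perceptually scaled metric hook), and picks the nearest target in
linear Hz. It reproduces the structural confusions of the task — /ɔ/
and /u/ share F2, so their confusions ride on F1 alone — and approaches
the 20% chance floor as noise grows.

**What passing simulations show.** The virtual subject has no learning,
fatigue, attention lapses, electrode artifacts, or muscle biomechanics,
and the virtual listener has no phonetic priors. Simulated healthy
intelligibility (~100%) therefore exceeds the human benchmark (>80%),
and the impaired profile's degradation (visual error up ~10×
healthy→CP in the worked example; fraction correct down to ~74%)
reproduces the *direction and tolerance* of the human effect — reaching
error grows much faster than intelligibility falls — not its printed
magnitudes. Tests accordingly pin exact arithmetic (table
reconstruction, κ calibration, protocol counts, resonator placement)
and assert only ordering/bounds for closed-loop outcomes.

## Problem sizes

Default test and acceptance runs use desk-scale sizes chosen as the
smallest that make the statistics stable: 10^5 Monte-Carlo trials for
listener calibration (±0.4% SE on fraction correct), 20 seeds for
drive-recovery error, 3–5 seeds × 5–25 trials for closed-loop session
properties, and 2–5-s traces at the native 1-kHz control rate.
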