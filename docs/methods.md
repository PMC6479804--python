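# Methods

## The problem

Savitzky–Golay (SG) filtering smooths a signal by least-squares polynomial
fitting inside a sliding window, which makes it attractive for ECG denoising:
it needs no frequency-domain design and handles nonstationary noise.  Its
weakness is the fixed polynomial order.  An ECG swings between near-flat
segments (best smoothed with a low order) and the sharp QRS complex (where a
low order clips the R peak).  Any single order trades noise suppression on
the flats against distortion at the peaks.

The adaptive filter implemented here selects the order per sample from a
discrete-curvature estimate of the local signal variation: flat regions get
low orders (strong smoothing), sharp features get high orders (faithful
tracking).  The window length stays fixed.

## Savitzky–Golay machinery (`core_sg`)

A window of `2M + 1` samples is indexed by integer offsets `n = -M..M`
(sample units; no rescaling by the sampling interval).  Fitting an order-`N`
polynomial `f(n) = sum_k a_k n^k` in the least-squares sense and evaluating
at the centre gives `y = a_0`, a linear function of the window — the dot
product with a fixed weight vector (the constant-coefficient row of the
design matrix's pseudo-inverse).

Numerically, the weights are computed from a QR factorisation of the
*even-power* block of the Vandermonde matrix: on symmetric integer abscissae
the even and odd monomials are Gram-orthogonal, so the centre value depends
only on even degrees.  This route is far better conditioned than
pseudo-inverting the full Vandermonde at high order (max error ~1e-12 for
`M <= 8` versus ~1e-7 via SVD pseudo-inverse at `M = 6, N = 12`), makes the
even/odd paired-order identity (`weights(M, 2k) == weights(M, 2k+1)`) hold
structurally, and the returned vector is symmetrised exactly (the true
solution is symmetric, so averaging with its reversal is a no-op in exact
arithmetic).  `0^0 := 1` so the constant column is all ones.  Weights always
sum to 1, hence constants pass through unchanged.

Edge samples (the first and last `M`, which lack a full window) are replaced
by evaluating a single least-squares polynomial fitted over the first/last
full window.  When called from the adaptive filter, the edge fit uses the
order selected for the nearest interior sample; standalone `sg_filter` uses
its own fixed order.  This choice is a convention of this package — edge
handling at the record boundary is otherwise underdetermined.

## Discrete curvature via digital straight segments (`curvature`)

The series is treated as a lattice curve `(i, x[i])`.  At sample `i` the
backward slope angle over distance `k` is `theta[i,k] =
arctan(|x[i] - x[i-k]| / k)` and the centred slope variation is
`delta[i,k] = theta[i+1,k] - theta[i-1,k]`, computed with `k = 2`
(the second neighbour).  A run of samples counts as one digital straight
segment (DSS) while every centred variation inside it stays within a
tolerance `delta`.  The backward DSS length `kb` is the largest `k <= km`
whose full predicate holds (a unit length is always accepted; near the
array bounds the scan truncates at the last computable variation);
symmetrically `kf` forward.  With Euclidean lengths `Lb, Lf` (time component
in samples) and segment angles `theta_b, theta_f`, the curvature is

    C_i = (Lb + Lf) (theta_b + theta_f) / (4 Lb Lf).

Properties and caveats, implemented and tested exactly as the formula
dictates:

- `C >= 0`, zero iff both segments are horizontal; invariant under constant
  offsets but **not** under amplitude scaling (angles are taken in raw
  signal units — `normalize_amplitude` is provided when scale invariance is
  wanted).
- Because the two angles are *summed*, a steep straight ramp has nonzero
  curvature; the estimator measures local steepness-and-shortness, not
  second-derivative curvature.
- Peak curvature is monotone in amplitude only while slope angles are far
  from saturation (peaks up to roughly 0.8 sample-units under the default
  parameters); for very large amplitudes the angle terms saturate at pi/2
  while the DSS lengths keep growing, so the response eventually decays.
  The test suite asserts monotonicity inside the monotone regime only.

The profile is defined on indices `[max(M, 3), n - 1 - max(M, 3)]` — three
neighbours per side are the minimum for one centred variation, and the
filter's own edge zone is excluded.  A vectorised run-length implementation
produces the profile; a literal nested-loop transcription of the search is
kept in the test suite and must agree bit-for-bit (both paths use the same
numpy elementary operations, since libm scalar routines can differ in the
last ulp).

### Choosing `delta` and `km`

`delta` encodes the slope deviation that noise alone can produce.  It must
sit **above** the noise-induced centred slope variation — otherwise every
DSS collapses to length 1 and the curvature profile tracks the noise rather
than the morphology — yet below the systematic slope change of a QRS
complex.  For an ECG with ~1 mV R peaks sampled at 360 Hz and contaminated
at 5–10 dB SNR, the noise-induced variation is of order 0.1–0.3 rad, so the
default is `delta = 0.4` rad.  At 0 dB it should be raised further.  With a
too-small `delta` the filter degrades gracefully toward noise-driven order
selection but loses its advantage at the R peaks.  `km = 10` samples
(~28 ms of context per side at 360 Hz) bounds the tangent support; larger
values over-smooth the curvature estimate near transitions.

## Adaptive filtering (`ldasg`)

The curvature profile of the *noisy* input (no pre-smoothing) is uniformly
quantised to integer orders:

    Order(n) = floor(N * C(n) / (Cmax - Cmin) + 1/2),  clamped to [1, N].

The numerator uses `C(n)` rather than `C(n) - Cmin`, so the clamp
reconciles the formula with the intended range `1..N`.  If `Cmax == Cmin`
(e.g. a constant or perfectly straight record) every sample gets
`fallback_order` (default 1: flat signals want maximal smoothing, and every
order preserves them anyway).  Edge-excluded indices inherit the order of
the nearest defined index.

The `N` candidate weight vectors are precomputed once (`N = 10` by default,
within the 9–20 band that suffices for uniform quantisation; window
`2M + 1 = 17` at 360 Hz, to be scaled proportionally for other sampling
rates).  Filtering is a per-sample dot product of the window with the
selected bank row; the first/last `M` samples come from the edge polynomial
fit at the nearest interior order.  The whole pipeline is deterministic and
length-preserving with no index shift.

## Noise model and synthetic ECG (`noise`)

Colored noise is white Gaussian noise shaped in the frequency domain to a
power spectral density `S(f) ∝ 1/f^beta` (`beta = 0` white, `1` pink); the
DC bin is zeroed and the draw is rescaled to exactly unit mean power.
Muscle-artifact (MA) noise is an input channel supplied by the caller; a
band-limited (20–120 Hz) Gaussian surrogate is provided for tests — it
matches the broadband spectral footprint of surface EMG but none of its
burst nonstationarity.  Contamination mixes the components in configurable
power proportions (equal thirds by default) and scales the sum so the
realised whole-record power SNR hits the target exactly.

The synthetic ECG is a quasi-periodic sum of five Gaussian bumps per beat
(P, Q, R, S, T), default 360 Hz, 72 bpm, R amplitude 1 (mV scale), widths
and offsets chosen to mimic textbook adult morphology (QRS ~40 ms wide,
PR ~200 ms, QT ~350 ms).  Beat anchors sit at `(k + 1/2) * RR` with optional
Gaussian RR jitter (0 by default, so beat counts are exact).  Ground-truth
R-peak indices are returned for distortion scoring.  What this generator
does *not* emulate: baseline wander, ectopic morphology changes, amplitude
modulation from respiration, and recorded-artifact nonstationarity — so
passing tests demonstrate the mechanism (curvature localises QRS, adaptive
orders reduce peak distortion) rather than clinical-grade performance on
real records.  Real WFDB records can be substituted everywhere via
`read_signal`.

## Metrics (`metrics`)

For clean `x` and denoised `y` over `K` samples: `SNRimp =
10 log10(sum x^2 / sum (y - x)^2)` (an output signal-to-distortion ratio;
at 0 dB input SNR it numerically equals the improvement), `MSE = mean
(y - x)^2`, and `PRD = 100 sqrt(sum (y - x)^2 / sum x^2)`, which is
algebraically `100 * 10^(-SNRimp/20)`.  Perfect reconstruction reports an
infinity sentinel for SNRimp rather than raising.

## Problem sizes and numerical conventions

Tests and the acceptance script use 10 s records at 360 Hz (3600 samples,
12 beats), three heart rates (60/72/90 bpm) for the benchmark grid, and
2^16-sample draws over 10 seeds for the spectral-slope contract.  Weight
identities are asserted at 1e-10, oracle equivalences at 1e-9 relative to
the window amplitude scale, realised SNR at 1e-9 dB, and the curvature
production/brute-force comparison at exact equality.  All randomness flows
through `numpy.random.default_rng` seeds; the benchmark spawns one child
stream per grid cell from a single `SeedSequence`.

## Known limitations

- Curvature (and hence order selection) is amplitude-scale dependent;
  records should be in a mV-like range or pre-normalised, and `delta`
  retuned when the scale changes.
- The fixed `delta` is a global noise-level assumption; heavily
  nonstationary noise would warrant a locally adapted tolerance, which is
  out of scope here.
- At 0 dB input SNR with the default `delta`, order selection degrades
  toward noise-driven choices; overall SNR improvement remains positive but
  the R-peak advantage over a fixed quadratic SG is no longer systematic.
- The filter bank stores duplicate rows for paired even/odd orders by
  construction; this is kept for index clarity rather than optimised away.
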