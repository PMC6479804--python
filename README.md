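# ldasg — curvature-adaptive Savitzky–Golay filtering for ECG denoising

Savitzky–Golay (SG) filters smooth a signal by least-squares polynomial
fitting in a sliding window of `2M+1` samples, equivalent to convolution
with fixed weights.  A single polynomial order cannot serve a whole ECG:
low orders clip the sharp QRS complex, high orders follow the noise on the
flat segments.  This package implements a low-distortion **adaptive** SG
filter that picks the order *per sample* from a discrete-curvature estimate
of the local signal variation, plus everything needed to evaluate it:
noise synthesis at exact SNR, a synthetic ECG generator, the standard
denoising metrics, and a benchmarking harness.  It is aimed at biomedical
signal-processing practitioners working with single-channel ECG from
clinical databases or wearable sensors.

## Method in brief

At each sample `i` the local tangent on either side is approximated by the
longest *digital straight segment* (DSS): the largest run `k ≤ k_m` of
samples whose centred slope-angle variations `δ_{j,2} = θ_{j+1,2} − θ_{j−1,2}`
(with `θ_{j,2} = arctan(|x_j − x_{j−2}|/2)`) all stay within a tolerance Δ.
With backward/forward DSS lengths `L_b, L_f` and slope angles `θ_b, θ_f`,
the discrete curvature is

    C_i = (L_b + L_f)(θ_b + θ_f) / (4 L_b L_f),

large at sharp features (R peaks), zero on flats.  The curvature profile is
uniformly quantised to polynomial orders

    Order(n) = floor( N·C(n) / (C_max − C_min) + 1/2 ),   clamped to [1, N],

and each sample is filtered with the precomputed central SG weight row of
its own order (window length fixed).  Denoising quality is scored by
SNR improvement `SNRimp = 10 log₁₀(Σx² / Σ(y−x)²)`, `MSE`, and
`PRD = 100·√(Σ(y−x)²/Σx²) = 100·10^(−SNRimp/20)`.

## Worked example

Simulate a 10 s, 72 bpm ECG contaminated with white Gaussian noise at 5 dB,
denoise it adaptively, and score the result:

```sh
$ ldasg simulate demo --noise-kind wgn --snr 5 --seed 1
wrote demo.{clean,noisy,noise}.csv and demo.json
$ ldasg denoise demo.noisy.csv demo.denoised.csv
denoised 3600 samples -> demo.denoised.csv
$ ldasg evaluate demo.clean.csv demo.denoised.csv
{
  "snr_imp": 14.954206492102657,
  "mse": 0.0011689557842575317,
  "prd": 17.876795635623598,
  "k": 3600
}
```

The noisy record enters at 5 dB; the denoised output sits at an output
signal-to-distortion ratio of ~15 dB — i.e. the residual error energy is
about 3% (PRD ≈ 17.9%) of the clean signal energy.  The same pipeline is
available as a library:

```python
from ldasg import (SyntheticECGSpec, NoiseSpec, LDASGConfig,
                   generate_ecg, contaminate, ldasg_denoise, evaluate)

clean, r_peaks = generate_ecg(SyntheticECGSpec(seed=1))
noisy, _ = contaminate(clean, NoiseSpec(kind="wgn", target_snr_db=5, seed=1))
denoised = ldasg_denoise(noisy, LDASGConfig(N=10, M=8))
print(evaluate(clean, denoised))
```

`ldasg benchmark` runs the full contaminate → denoise → score grid over
records × SNR levels (with a fixed-order SG baseline for comparison), and
`ldasg curvature` emits the per-sample curvature profile for inspection.

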