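# blurage

Motion-blur-robust facial age estimation.

Hand-held cameras and moving subjects leave linear motion blur on face
images, and age estimators trained on sharp faces degrade badly on
them. `blurage` implements the full counter-measure pipeline:

1. **Blur parameter estimation.** A linear motion blur of length *L*
   pixels at direction *θ* multiplies the image spectrum by
   `H(u,v) = sinc(πL(u cosθ + v sinθ))`. Its bright central ridge runs
   orthogonal to the motion and its nulls repeat every `d = N/L`
   frequency bins. The direction is found with a Radon transform of
   the Hann-windowed log power spectrum restricted to a circle, pooled
   over a band of offsets per angle (`P(θ) = Σ_ρ R(ρ,θ)`, the ρ-range
   summation); the length is recovered by least-squares fitting a
   log-sinc² model to the spectral profile along the motion direction
   and reading `L = N/d`.
2. **Focused/blurred classification.** The focus score
   `FS = 100·S_{θ+90}/S_θ` compares the spectral mass orthogonal to the
   dominant ridge against the ridge itself: isotropic (sharp) spectra
   score near 100, blurred ones much lower. A decision threshold is
   learned from training scores.
3. **Per-blur-group age estimation.** Images are routed to one of nine
   groups — focused, and {slight, blurred} × {0°, 45°, 90°, 135°} —
   and each group gets its own age model: multi-level local binary
   pattern histograms (global texture) fused with Gabor wrinkle
   statistics from five facial regions (forehead, eye corners,
   under-eye), Z-score normalized, PCA-reduced, and regressed with an
   RBF support-vector machine. Performance is reported as the mean
   absolute error `MAE = (1/N) Σ |a'_k − a_k|` in years.

Because face databases with age labels are licensed, the package ships
seeded synthetic generators (`blurage.synthetic`): broadband textures
for the blur estimators and face-like images whose wrinkle amplitude
and frequency grow with a latent age, which all tests and benchmarks
run on.

## Worked example

`examples/estimate_blur_parameters.py` blurs a synthetic texture with a
known kernel (θ = 45°, L = 9) and recovers the parameters:

```
true direction / length :   45.0 deg / 9
estimated direction     :   45.0 deg
null spacing d          :  30.16 spectrum pixels
estimated length        :   8.49 raw -> 9 snapped
```

The direction is read off the dominant spectral ridge; the null
spacing 30.16 gives a raw length of 256/30.16 ≈ 8.49, snapped to the
protocol's odd length grid. `examples/focus_score_classification.py`
shows the score separation that drives blur classification:

```
focus scores, sharp   : min  94.72  max  99.19
focus scores, blurred : min  45.11  max  79.04
learned threshold     :  86.88
held-out EER          :  0.000 %
```

and `examples/age_pipeline_demo.py` trains the grouped registry on a
handful of synthetic faces and routes a blurred holdout face to its
matching group:

```
focus threshold learned on training grid: 79.65
sharp face   : true age  81.3  predicted  68.1  group focused
blurred face : true age  81.3  predicted  67.0  group slight-45  (estimated theta 45 deg, length 7)
```

(Prediction accuracy improves with training-set size; the demo uses 15
faces to stay fast.)

There is also a thin CLI: `blurage estimate-blur <image>`,
`blurage make-fixtures`, `blurage train / predict / evaluate`, and
`blurage config show` to print every tunable and the configuration
hash recorded in trained model archives.

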