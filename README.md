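# flagkin

Waveform kinematics and energetics of head-tethered sperm flagella.

Mouse sperm motility studies increasingly score flagellar function from
high-speed dark-field video of sperm whose heads adhere to the slide: the
tail beats in place, and the beat's geometry and mechanics can be measured
at high resolution. `flagkin` implements that full analysis chain for
planar beats, together with a synthetic beat-and-video generator so every
stage can be exercised, and its accuracy quantified, without real
recordings:

* **Centerline tracing** — per-frame segmentation, skeletonization,
  ridge-refined spline fitting and uniform arc-length resampling of the
  flagellum from multi-page TIFF stacks.
* **Waveform representation** — the tangent angle ψ(s, t) on an arc-length ×
  time grid, with the curvature kymograph κ(s, t) = ∂ψ/∂s.
* **Kinematics** — beat frequency from curvature turning points at 50% and
  75% of the tail length; per-section amplitudes (head 6.3 µm, midpiece
  22.4 µm, principal piece 80 µm set points); a four-level midpiece
  flexibility classification (highly stiff < 6 µm, moderately stiff 6–16 µm,
  relatively flexible 16–27 µm, highly flexible ≥ 27 µm).
* **Shape modes** — SVD of the centered waveform; the two dominant
  coefficients B₁(t), B₂(t) trace a circle for a periodic beat, and a
  circularity score quantifies beat-to-beat reproducibility.
* **Energetics** — resistive-force-theory drag (ξ_t, ξ_n per unit length),
  Euler–Bernoulli elasticity (EI), internal cross-sectional friction (η_i),
  and recovery of the active dynein moment m_a(s, t) from quasi-static force
  balance, yielding motor input P_in, motor dissipation D_m, internal
  dissipation D_i and hydrodynamic dissipation D_h (with midpiece /
  principal-piece split), reported as cycle averages in fW.
* **Population pipeline** — labelled synthetic populations driven by mixture
  weights over the flexibility categories, per-recording QC, population
  breakdowns, and genotype comparisons using an unpaired Student t-test on
  per-animal means.

The synthetic generator produces beats directly in the tangent-angle
representation, ψ(s, t) = A(s)·sin(2π(f·t − s/λ) + φ₀), stepped into
inextensible head-clamped centerlines and rendered as dark-field-like uint16
stacks (Gaussian PSF, Poisson shot noise, Gaussian read noise) with the
ground truth attached.

## Worked example

```python
from flagkin import (BeatParams, OpticsParams, beat_frequency,
                     curvature_kymograph, classify_flexibility,
                     render_frames, section_amplitude, simulate_beat,
                     to_waveform, trace_scene)

params = BeatParams(beat_frequency=4.0, duration=1.0, fps=100.0, seed=3)
series = simulate_beat(params, ds=1.0)                 # ground truth
scene = render_frames(series, OpticsParams.for_snr(10.0), seed=3)

traced, qc = trace_scene(scene)                        # image -> centerlines
w = to_waveform(traced)
print(round(beat_frequency(curvature_kymograph(w)), 2))  # 3.99  (Hz)
amps = section_amplitude(traced)
print(round(amps["mid"], 1))                             # 41.9  (µm)
print(classify_flexibility(amps["mid"]).value)           # highly_flexible
```

The frequency comes back at the generated 4 Hz, the traced midpiece
amplitude (41.9 µm) agrees with the ground-truth 42.0 µm at crest SNR 10,
and the cell classifies as highly flexible.
The scripts in `examples/` walk through each capability the same way
(simulation and rendering, tracing and classification, shape cycles,
energetics, population studies) and print the numbers they compute.

A thin CLI wraps the same functions for shell use:

```bash
flagkin simulate --config run.yaml --out sim/ --seed 1
flagkin trace    --stack sim/cell0000.tif --out traced/
flagkin analyze  --input sim/cell0000.tif --out analysis/
flagkin report   --records cells.csv --out report/
```

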