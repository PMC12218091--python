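"""Shape-mode decomposition and the B1-B2 shape cycle.

A periodic traveling-wave beat is captured almost entirely by two spatial
modes whose coefficients trace a circle; injecting phase jitter (irregular
beating) degrades the circle and lowers the circularity score.
"""

from flagkin import BeatParams, analytic_waveform, fit_shape_modes

regular = BeatParams(beat_frequency=5.0, duration=2.0, fps=250.0, seed=5)
jittery = BeatParams(beat_frequency=5.0, duration=2.0, fps=250.0, seed=5,
                     phase_jitter=2.0, amplitude_jitter=0.25)

for name, params in [("regular", regular), ("irregular", jittery)]:
    cycle = fit_shape_modes(analytic_waveform(params, ds=1.0), k=2)
    v1, v2 = cycle.variance_explained[:2]
    print(f"{name:15s} modes explain {100 * (v1 + v2):.1f}% of variance, "
          f"circularity = {cycle.circularity:.2f}")
# the regular beat gives >99% two-mode variance and circularity ~1;
# phase jitter spreads the orbit radius and lowers the score
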