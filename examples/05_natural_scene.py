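"""Naturalistic viewing: saccades, fixational jitter, and scene assembly.

Encodes a 1/f natural-statistics scene through a simulated gaze (saccades to
high-spatial-frequency regions, optional Brownian fixational jitter), with a
rank-1 spatiotemporal reconstruction filter, and reassembles the scene by
averaging the per-frame patch reconstructions.  Compares how many saccades
each condition needs to reach the same assembled-scene error.
"""

from dither.protocols import dynamic_jitter_study

df = dynamic_jitter_study(seed=1, n_fixations=60, choices_per_frame=12,
                          n_replicates=2)
print(df.round(3).to_string(index=False))
print(f"mean saccade-count ratio (without / with jitter) at matched error: "
      f"{df.ratio.mean():.1f}x")
print("Fixational jitter shifts the mosaic across the scene within each "
      "fixation, so averaging sharpens the assembly with far fewer saccades.")
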