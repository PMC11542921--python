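"""Data-driven hardware efficiency: drop rarely used electrodes.

Ranks electrodes by how often greedy dithering stimulates them on a training
set of targets, then re-encodes held-out targets with dictionaries restricted
to the top fractions of electrodes, alongside the convex lower bound.
"""

from dither.protocols import subsampling_study

curve = subsampling_study(seed=1, n_targets=10, T_max=10_000,
                          fractions=(0.2, 0.5, 1.0))
print(curve.round(4).to_string(index=False))
half = curve.set_index("fraction")
inc = (half.loc[0.5, "greedy_error"] / half.loc[1.0, "greedy_error"] - 1)
print(f"keeping the most-used half of the electrodes raises held-out error "
      f"by only {inc:.1%} -- a candidate power saving for an implant.")
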