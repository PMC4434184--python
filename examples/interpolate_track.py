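"""Upsample a 10-bp-resolution occupancy track to per-bp by cubic spline.

Builds a coarse track with a smooth depletion dip, splines it, and checks
that the interpolant passes through every bin-midpoint knot while filling
in the per-bp values between them.
"""

import numpy as np

from nucbend import CoarseTrack, spline_interpolate

starts = np.arange(0, 600, 10)
mids = starts + 5.0
values = 1.0 - 0.5 * np.exp(-0.5 * ((mids - 300) / 60.0) ** 2)  # dip at 300
coarse = CoarseTrack("chr1", starts, starts + 10, values)

fine = spline_interpolate(coarse)
knot_err = max(abs(fine.value_at(int(m)) - v) for m, v in zip(mids, values))
print(f"{len(coarse)} bins of 10 bp -> {np.isfinite(fine.values).sum()} per-bp values")
print(f"max |spline - knot| at the {len(coarse)} knots: {knot_err:.2e}")
print(f"value between knots, position 303: {fine.value_at(303):.4f} (knots 1 bp apart differ smoothly)")
print(
    "The spline reproduces each 10-bp bin value exactly at its midpoint and "
    "gives a smooth per-bp curve in between -- the form the metaprofile and "
    "per-feature averaging stages consume."
)
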