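"""Package-wide defaults.

All quantities a downstream analysis might want to override live here, with
units in the names. Functions take these as keyword defaults rather than
reading global state, so overriding per-call is always possible.
"""

#: Retinal sampling of the instrument, µm per pixel. 50 µm / 65 px, so the
#: standard 50 x 50 µm sampling window is exactly 65 x 65 px.
PIXEL_SCALE_UM = 50.0 / 65.0

#: Side of a sampling window, µm.
WINDOW_SIDE_UM = 50.0

#: Diagonal displacement of the TL/TR/BL/BR windows from Mid, µm.
WINDOW_OFFSET_UM = 25.0

#: 5-point discrete Laplacian — the canonical kernel behind the
#: energy-of-Laplacian (LAPE) focus measure.
LAPLACIAN_5PT = ((0.0, 1.0, 0.0), (1.0, -4.0, 1.0), (0.0, 1.0, 0.0))

#: 8-neighbour Laplacian variant.
LAPLACIAN_8PT = ((1.0, 1.0, 1.0), (1.0, -8.0, 1.0), (1.0, 1.0, 1.0))

#: Reference mean intensity after brightness normalization (on a [0, 1] scale).
BRIGHTNESS_REFERENCE = 0.5

#: Multiplier taking mean per-pixel Laplacian energy to the instrument's
#: 0-75 focus scale. Calibrated once against the default synthetic cohort:
#: the 99th percentile of cohort scores sits at 75, and sharp low-eccentricity
#: mosaics span the upper part of the range. See docs/methods.md.
LAPE_CALIBRATION = 570.0

#: Intensity at or below which a pixel counts as outside the mosaic.
BLANK_THRESHOLD = 0.0

#: Truncated-area fraction above which a patch is category 1.
TRUNCATION_LIMIT = 0.05

#: Global defocus blur (µm) beyond which cones are considered unresolvable
#: everywhere, making an untruncated patch category 2. Rayleigh-like limit:
#: the instrument cannot distinguish structure of 2 µm or less.
UNRESOLVABLE_BLUR_UM = 2.5

#: Amplitude factor applied to cones in a degraded quadrant.
QUADRANT_SUPPRESSION = 0.05

#: Default Loess span (fraction of the 751-point score grid).
LOESS_SPAN = 0.3
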