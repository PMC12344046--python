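"""Gradation: stored scanner values -> CT numbers -> windowed 16-bit display.

Builds a tiny synthetic slice with the standard rescale (slope 1, intercept
-1000) and windows it at center 0 / width 2000 HU, then shows the round trip
to the [0, 1] range the network consumes.
"""

import numpy as np

from ossr import (RawScanSlice, WindowSettings, ct_to_display, denormalize,
                  normalize, raw_to_ct, window_minimum)

# stored values for air, water and calcium-dense bone under intercept -1000
raw = RawScanSlice(pixels=np.array([[0, 1000, 2000]]),
                   rescale_slope=1.0, rescale_intercept=-1000.0,
                   window_center=0.0, window_width=2000.0)

ct = raw_to_ct(raw)
print("CT numbers (HU):", ct[0])          # -1000 (air), 0 (water), 1000

window = WindowSettings(center=0.0, width=2000.0)
print("window minimum (HU):", window_minimum(window))  # -1000

display = ct_to_display(ct, window)
print("display values:", display[0])       # 0 .. 65025 across the window

norm = normalize(display)
print("normalized:", np.round(norm[0], 4))
print("round trip exact:", bool(np.array_equal(denormalize(norm), display)))
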