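"""Differential box-counting: rough blocks get larger WRHOG weights.

Prints the DBC fractal dimension of three 16x16 blocks - flat, smooth
gradient, and ridge texture.  D = 2 exactly for a flat block and grows
toward 3 with surface roughness; WRHOG multiplies each block's histogram
by its D, so information-dense blocks count for more in matching.
"""

import numpy as np

from vowrhog import fractal_dimension

flat = np.full((16, 16), 128.0)
smooth = np.tile(np.linspace(100, 160, 16), (16, 1))
rows, cols = np.indices((16, 16)).astype(float)
ridges = 128 + 35 * np.cos(2 * np.pi * 0.2 * (cols * 0.8 + rows * 0.6))
noise = np.random.default_rng(0).uniform(0, 255, (16, 16))

for name, blk in [("flat", flat), ("smooth ramp", smooth),
                  ("ridge texture", ridges), ("uniform noise", noise)]:
    print(f"{name:14s} D = {fractal_dimension(blk):.3f}")
print("\nD orders the blocks by surface roughness: flat=2 exactly, noise ~2.5+.")
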