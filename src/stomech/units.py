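"""Physical calibration constants of the imaging setup.

The confocal acquisition has a fixed in-plane pixel area and axial step;
all pixel/voxel to micrometre conversions in the package go through these
constants (areas scale with ``PIXEL_AREA_UM2``, lengths with its square
root).
"""

import math

#: Physical area of one XY pixel (μm²).
PIXEL_AREA_UM2: float = 0.0409

#: Side length of one XY pixel (μm); lengths in pixels × this = μm.
PIXEL_SIZE_UM: float = math.sqrt(PIXEL_AREA_UM2)

#: Axial (Z) step between slices (μm).
Z_STEP_UM: float = 0.2
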