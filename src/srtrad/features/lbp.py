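"""Local binary pattern parametric maps.

The LBP code of a voxel compares it with its 8 in-plane neighbours
(P=8, R=1) on each axial slice independently; arrays are indexed (x, y, z)
with axial slices ``image[:, :, k]``. The neighbour ordering is fixed and
documented: starting east of the centre and proceeding clockwise in (x, y)
coordinates —

    bit 0: (x+1, y)    bit 1: (x+1, y-1)  bit 2: (x, y-1)  bit 3: (x-1, y-1)
    bit 4: (x-1, y)    bit 5: (x-1, y+1)  bit 6: (x, y+1)  bit 7: (x+1, y+1)

A bit is set when the neighbour intensity is >= the centre intensity, so the
map is invariant to strictly increasing intensity transforms. Slice borders
are handled by edge replication, making border comparisons self-comparisons
(bit set). Codes are raw 8-bit values in [0, 255] (not rotation invariant).
"""

from __future__ import annotations

import numpy as np

#: (dx, dy) per bit, clockwise from east
NEIGHBOUR_OFFSETS = (
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
)


def lbp_map(image: np.ndarray) -> np.ndarray:
    """Per-voxel 2D LBP codes of a 3D image, slice by slice along axis 2."""
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("expected a 3D image")
    padded = np.pad(image, ((1, 1), (1, 1), (0, 0)), mode="edge")
    codes = np.zeros(image.shape, dtype=np.uint8)
    centre = padded[1:-1, 1:-1, :]
    for bit, (dx, dy) in enumerate(NEIGHBOUR_OFFSETS):
        neigh = padded[1 + dx : padded.shape[0] - 1 + dx, 1 + dy : padded.shape[1] - 1 + dy, :]
        codes |= (neigh >= centre).astype(np.uint8) << bit
    return codes
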