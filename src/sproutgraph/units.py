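"""Small unit-conversion helpers shared across the package.

All physical lengths in the public API are micrometres; pixel quantities
are converted through the image calibration (μm per pixel).
"""

from __future__ import annotations

#: Default image calibration in μm per pixel.
DEFAULT_RESOLUTION_UM_PER_PX = 1.25

#: Default bead radius in μm (265 μm diameter microcarrier beads).
DEFAULT_BEAD_RADIUS_UM = 132.5


def px_to_um(px: float, resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX) -> float:
    """Convert a pixel length to micrometres."""
    if resolution_um_per_px <= 0:
        raise ValueError("resolution must be positive")
    return px * resolution_um_per_px


def um_to_px(um: float, resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX) -> float:
    """Convert a micrometre length to (fractional) pixels."""
    if resolution_um_per_px <= 0:
        raise ValueError("resolution must be positive")
    return um / resolution_um_per_px
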