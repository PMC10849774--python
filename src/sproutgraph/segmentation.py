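"""Foreground segmentation of bead-sprouting images.

The recipe: Gaussian blur (11-px kernel) → global threshold at 1.17× the
mean of the blurred image → fill small holes (boundary < 200 px) → keep the
largest connected component → detect the central bead by morphological
opening with a disk → remove the bead disk to leave the sprout mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import isotropic_opening

from .imaging_io import CalibratedImage
from .units import DEFAULT_BEAD_RADIUS_UM

DEFAULT_BLUR_KERNEL_PX = 11
DEFAULT_THRESHOLD_FACTOR = 1.17
DEFAULT_HOLE_PERIMETER_PX = 200
DEFAULT_BEAD_MARGIN_PX = 2
#: Opening structuring-element radius as a fraction of the expected bead radius.
BEAD_ELEMENT_FACTOR = 0.8

_STRUCT8 = np.ones((3, 3), bool)  # 8-connectivity for foreground


class BeadDetectionError(RuntimeError):
    """Raised when no bead-sized blob can be located."""


@dataclass(frozen=True)
class Circle:
    """A circle in pixel coordinates, (row, col) center."""

    center: tuple[float, float]
    radius: float


@dataclass
class SegmentationResult:
    """Foreground mask, detected bead, and the sprout mask (foreground minus bead)."""

    foreground: np.ndarray
    bead: Circle
    sprout_mask: np.ndarray
    bead_region: np.ndarray  # foreground ∩ removed bead disk (supports A_c)
    parameters: dict = field(default_factory=dict)


def segment(
    img: CalibratedImage,
    blur_kernel_px: int = DEFAULT_BLUR_KERNEL_PX,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
) -> np.ndarray:
    """Blur and threshold: foreground = blurred intensity strictly above
    ``threshold_factor`` × the global mean of the blurred image.

    The "kernel of size 11 pixels" is an 11×11 Gaussian window, realised as
    ``gaussian_filter`` with σ = kernel/6 and support truncated to the
    half-width of the window.
    """
    sigma = blur_kernel_px / 6.0
    radius = blur_kernel_px // 2
    blurred = ndimage.gaussian_filter(img.pixels, sigma=sigma, truncate=radius / sigma)
    mean = blurred.mean()
    fg = blurred > threshold_factor * mean
    if not fg.any():
        warnings.warn("segmentation produced an empty foreground", stacklevel=2)
    return fg


def hole_boundary_length(hole: np.ndarray, foreground: np.ndarray) -> int:
    """Boundary length of a hole: count of hole pixels with ≥1 foreground
    8-neighbor.  The same tracer is used by the filter and by test oracles."""
    dilated_fg = ndimage.binary_dilation(foreground, structure=_STRUCT8)
    return int(np.count_nonzero(hole & dilated_fg))


def fill_holes(mask: np.ndarray, max_perimeter_px: int = DEFAULT_HOLE_PERIMETER_PX) -> np.ndarray:
    """Fill background components not connected to the border whose boundary
    length is below ``max_perimeter_px``; larger holes are left untouched."""
    mask = np.asarray(mask, dtype=bool)
    background = ~mask
    # 4-connectivity for background complements 8-connected foreground
    labels, n = ndimage.label(background, structure=ndimage.generate_binary_structure(2, 1))
    if n == 0:
        return mask.copy()
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border_labels = set(border_labels.tolist()) - {0}
    out = mask.copy()
    for lab in range(1, n + 1):
        if lab in border_labels:
            continue
        hole = labels == lab
        if hole_boundary_length(hole, mask) < max_perimeter_px:
            out[hole] = True
    return out


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties are broken by the component containing the smallest (row, col)
    pixel in scan order.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask.copy()
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    best = np.max(sizes)
    candidates = [i + 1 for i, s in enumerate(sizes) if s == best]
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        # scipy labels in scan order, so the smallest candidate label is the
        # component whose first pixel comes first in scan order
        keep = min(candidates)
    return labels == keep


def detect_bead(
    img: CalibratedImage,
    mask: np.ndarray,
    expected_radius_um: float = DEFAULT_BEAD_RADIUS_UM,
) -> Circle:
    """Locate the central bead in the foreground mask.

    A morphological opening with a disk sized from the expected bead radius
    erases the thin sprouts; the surviving blob (the complement of the
    top-hat) is the bead body.  Center = blob centroid, radius = its
    equivalent-area radius.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise BeadDetectionError("empty mask")
    expected_radius_px = expected_radius_um / img.resolution_um_per_px
    element_radius = BEAD_ELEMENT_FACTOR * expected_radius_px
    opened = isotropic_opening(mask, radius=element_radius)
    labels, n = ndimage.label(opened, structure=_STRUCT8)
    min_area = 0.25 * np.pi * expected_radius_px**2
    if n == 0:
        raise BeadDetectionError("no bead-sized blob found")
    sizes = ndimage.sum_labels(opened, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        raise BeadDetectionError(
            f"dominant blob area {sizes[best - 1]:.0f} px < quarter of expected bead area"
        )
    blob = labels == best
    rows, cols = np.nonzero(blob)
    center = (float(rows.mean()), float(cols.mean()))
    radius = float(np.sqrt(blob.sum() / np.pi))
    return Circle(center=center, radius=radius)


def remove_bead(
    mask: np.ndarray,
    bead: Circle,
    margin_px: float = DEFAULT_BEAD_MARGIN_PX,
) -> tuple[np.ndarray, np.ndarray]:
    """Clear all pixels within ``bead.radius + margin_px`` of the bead center.

    Returns ``(sprout_mask, bead_region)`` where ``bead_region`` is the
    foreground inside the cleared disk (the support of the A_c metric).
    """
    mask = np.asarray(mask, dtype=bool)
    rr, cc = np.ogrid[: mask.shape[0], : mask.shape[1]]
    dist2 = (rr - bead.center[0]) ** 2 + (cc - bead.center[1]) ** 2
    disk = dist2 <= (bead.radius + margin_px) ** 2
    bead_region = mask & disk
    sprout_mask = mask & ~disk
    return sprout_mask, bead_region


def segment_image(
    img: CalibratedImage,
    blur_kernel_px: int = DEFAULT_BLUR_KERNEL_PX,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    hole_perimeter_px: int = DEFAULT_HOLE_PERIMETER_PX,
    expected_bead_radius_um: float = DEFAULT_BEAD_RADIUS_UM,
    bead_margin_px: float = DEFAULT_BEAD_MARGIN_PX,
) -> SegmentationResult:
    """Full segmentation stage: threshold, fill, largest component, bead
    detection and removal."""
    fg = segment(img, blur_kernel_px, threshold_factor)
    fg = fill_holes(fg, hole_perimeter_px)
    fg = largest_component(fg)
    bead = detect_bead(img, fg, expected_bead_radius_um)
    sprout_mask, bead_region = remove_bead(fg, bead, bead_margin_px)
    return SegmentationResult(
        foreground=fg,
        bead=bead,
        sprout_mask=sprout_mask,
        bead_region=bead_region,
        parameters={
            "blur_kernel_px": blur_kernel_px,
            "threshold_factor": threshold_factor,
            "hole_perimeter_px": hole_perimeter_px,
            "expected_bead_radius_um": expected_bead_radius_um,
            "bead_margin_px": bead_margin_px,
        },
    )
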