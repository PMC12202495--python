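"""Shared image operators for the quantification pipelines.

These primitives mirror the classic FIJI-style punctate-signal workflow:
maximum-intensity z-projection, rolling median-background subtraction,
histogram auto-thresholding (IsoData by default, Otsu as an alternative),
distance-transform watershed to split touching particles, and calibrated
connected-component measurement.

All images are 2D ``float64`` arrays internally; intensities are in
arbitrary units (a.u.) and sizes are calibrated through ``pixel_size``
(µm/px). Coordinates are 0-based, row-major, with 8-connectivity for
component labeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_isodata, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

__all__ = [
    "LabeledStack",
    "BinaryMask",
    "Particle",
    "ParticleSet",
    "z_project",
    "median_subtract",
    "auto_threshold",
    "watershed_split",
    "label_particles",
]

#: channel roles a stack may carry
ROLES = ("marker", "target", "nuclear")


@dataclass
class LabeledStack:
    """A calibrated multi-channel fluorescence z-stack.

    Parameters
    ----------
    voxels
        Array of shape ``(n_channels, n_slices, rows, cols)``, intensity a.u.
    channel_roles
        Map from role (``marker`` — cell-type stain such as GFAP or MAP2;
        ``target`` — the quantified stain such as TOMM20 or MCT4;
        ``nuclear`` — DNA counterstain) to channel index.
    pixel_size
        Lateral calibration in µm per pixel.
    slice_spacing
        Axial distance between consecutive slices in µm.
    """

    voxels: np.ndarray
    channel_roles: dict[str, int]
    pixel_size: float
    slice_spacing: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be (channels, slices, rows, cols), got shape {self.voxels.shape}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be > 0")
        n_chan = self.voxels.shape[0]
        indices = list(self.channel_roles.values())
        if len(set(indices)) != len(indices):
            raise ValueError("channel_roles must be injective (one channel per role)")
        for role, idx in self.channel_roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown channel role {role!r}; expected one of {ROLES}")
            if not 0 <= idx < n_chan:
                raise ValueError(f"channel index {idx} for role {role!r} out of range")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.voxels.shape[2], self.voxels.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(slices, rows, cols)`` sub-stack for a role."""
        if role not in self.channel_roles:
            raise KeyError(f"stack has no channel with role {role!r}")
        return self.voxels[self.channel_roles[role]]


@dataclass
class BinaryMask:
    """A thresholded 2D image with its calibration.

    ``area_um2`` is always the true-pixel count × ``pixel_size``².
    """

    mask: np.ndarray
    pixel_size: float
    threshold: float | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pixel_size**2


@dataclass(frozen=True)
class Particle:
    """One detected particle: calibrated area and pixel-space centroid."""

    area_um2: float
    centroid: tuple[float, float]  # (row, col) in px
    n_pixels: int
    label: int


@dataclass
class ParticleSet:
    """Detected particles with the calibration and filters applied to them."""

    particles: list[Particle]
    pixel_size: float
    min_area_applied: float = 0.0

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([p.area_um2 for p in self.particles], dtype=float)

    @property
    def centroids(self) -> np.ndarray:
        if not self.particles:
            return np.empty((0, 2))
        return np.array([p.centroid for p in self.particles], dtype=float)


def z_project(
    stack: LabeledStack,
    channel: str,
    slice_range: tuple[int, int] | None = None,
    method: str = "max",
) -> np.ndarray:
    """Collapse a channel's z-slices into a 2D image.

    ``slice_range`` is a half-open ``(start, stop)`` interval over slice
    indices; ``None`` uses all slices. ``method`` is ``"max"`` (default,
    the usual choice for punctate signal) or ``"mean"``.
    """
    sub = stack.channel(channel)
    if slice_range is not None:
        start, stop = slice_range
        if not (0 <= start < stop <= stack.n_slices):
            raise ValueError(
                f"slice_range {slice_range} invalid for stack with {stack.n_slices} slices"
            )
        sub = sub[start:stop]
    if sub.shape[0] == 0:
        raise ValueError("empty slice_range")
    if method == "max":
        return sub.max(axis=0)
    if method == "mean":
        return sub.mean(axis=0)
    raise ValueError(f"unknown projection method {method!r}; expected 'max' or 'mean'")


def median_subtract(image: np.ndarray, radius_px: int = 4) -> np.ndarray:
    """Subtract a disk-footprint median filter from the image, clipping at 0.

    Removes smooth background (autofluorescence, uneven illumination)
    while leaving features smaller than the footprint mostly intact.
    Boundary handling is reflect padding.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(image.shape):
        raise ValueError(
            f"median filter footprint (radius {radius_px}) exceeds image shape {image.shape}"
        )
    background = ndi.median_filter(image, footprint=disk(radius_px), mode="reflect")
    return np.clip(image - background, 0.0, None)


def auto_threshold(
    image: np.ndarray,
    pixel_size: float,
    method: str = "isodata",
) -> BinaryMask:
    """Auto-threshold an image into a binary mask.

    ``method`` is ``"isodata"`` (iterative intermeans, the FIJI "Default"
    family) or ``"otsu"``. The computed threshold is stored on the result;
    foreground is strictly ``image > t``. A constant image has no defined
    threshold: an empty mask is returned with a warning.

    The isodata criterion can admit several intermeans fixed points when a
    background-subtracted image carries a dominant clipped-at-zero bin in
    addition to its noise and signal modes; the *largest* fixed point is
    used, which separates signal from everything below it (on a clean
    two-level histogram there is only one fixed point, so the choice is
    inert there).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if np.ptp(image) == 0:
        warnings.warn(
            "auto_threshold: constant image, threshold undefined; returning empty mask",
            stacklevel=2,
        )
        return BinaryMask(np.zeros(image.shape, bool), pixel_size, threshold=None, method=method)
    if method == "isodata":
        t = float(np.atleast_1d(threshold_isodata(image, return_all=True))[-1])
    elif method == "otsu":
        t = float(threshold_otsu(image))
    else:
        raise ValueError(f"unknown threshold method {method!r}; expected 'isodata' or 'otsu'")
    return BinaryMask(image > t, pixel_size, threshold=t, method=method)


def watershed_split(mask: BinaryMask, min_seed_distance: int = 2) -> np.ndarray:
    """Split touching convex blobs with a Euclidean-distance-transform watershed.

    Seeds are the local-maximum plateaus of the distance map: pixels whose
    distance equals the maximum within a ``min_seed_distance``-radius disk.
    A connected plateau (e.g. the ridge of a single blob, however shaped)
    collapses to one seed, so isolated blobs are never oversplit, while two
    touching convex blobs keep two separated plateaus and are split at the
    distance-map saddle. Deterministic (no tie-breaking randomness).
    Watershed separation lines are labeled 0 and excluded from downstream
    pixel counts, by convention.

    Returns an integer label image; label count >= connected-component count.
    """
    fg = mask.mask
    labels_out = np.zeros(fg.shape, dtype=np.int32)
    if not fg.any():
        return labels_out
    structure = np.ones((3, 3), bool)  # 8-connectivity
    distance = ndi.distance_transform_edt(fg)
    local_max = ndi.maximum_filter(distance, footprint=disk(min_seed_distance))
    seed_mask = fg & (distance >= local_max)
    markers, _ = ndi.label(seed_mask, structure=structure)
    return watershed(-distance, markers, mask=fg, watershed_line=True).astype(np.int32)


def label_particles(labels: np.ndarray, pixel_size: float) -> ParticleSet:
    """Measure labeled regions: calibrated area and centroid per label."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    labels = np.asarray(labels)
    particles = [
        Particle(
            area_um2=float(rp.area) * pixel_size**2,
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            n_pixels=int(rp.area),
            label=int(rp.label),
        )
        for rp in regionprops(labels)
    ]
    return ParticleSet(particles=particles, pixel_size=pixel_size)
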