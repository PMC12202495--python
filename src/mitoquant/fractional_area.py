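"""Fractional immunoreactive area within manually annotated cells.

The statistic: for each annotated cell, the fraction of its pixels whose
target-channel intensity (e.g. the lactate transporter MCT4) exceeds a
background-derived threshold. The threshold is the mean of three
background intensity measurements in the same image multiplied by a
signal-to-noise ratio (SNR). The comparison is strict (">"): a pixel at
exactly the threshold does not count as positive.

The SNR is an explicit per-image input (default 3.0); an optional
estimator — mean intensity of the top-decile pixels inside annotated
cells divided by the background mean — is provided for images without a
recorded value and is always reported alongside the result.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

__all__ = [
    "CellAnnotation",
    "FractionalAreaResult",
    "compute_threshold",
    "estimate_snr",
    "fractional_area",
    "group_summary",
    "annotations_from_geojson",
]

#: the selection rule used when choosing analysis regions: at least this
#: many cells of the relevant type per region (enforced as a warning)
MIN_CELLS_PER_REGION = 15


@dataclass
class CellAnnotation:
    """One manually annotated cell: a boolean pixel mask plus identity."""

    mask: np.ndarray
    cell_type: str
    cell_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("annotation mask must be 2D")
        if not self.mask.any():
            raise ValueError(f"annotation {self.cell_id} has zero area")

    @classmethod
    def from_polygon(
        cls,
        vertices: np.ndarray,
        shape: tuple[int, int],
        cell_type: str,
        cell_id: str,
    ) -> "CellAnnotation":
        """Rasterize a polygon given as (row, col) vertices onto an image shape."""
        vertices = np.asarray(vertices, dtype=float)
        rr, cc = draw_polygon(vertices[:, 0], vertices[:, 1], shape=shape)
        mask = np.zeros(shape, bool)
        mask[rr, cc] = True
        return cls(mask=mask, cell_type=cell_type, cell_id=cell_id)


@dataclass
class FractionalAreaResult:
    cell_id: str
    cell_type: str
    fraction: float
    threshold: float
    background_mean: float
    snr: float
    n_pixels: int


def compute_threshold(
    background_samples: np.ndarray, snr: float, expected_n: int = 3
) -> float:
    """Threshold = mean of the background measurements × signal-to-noise ratio."""
    bg = np.asarray(background_samples, dtype=float)
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if bg.size != expected_n:
        warnings.warn(
            f"expected {expected_n} background measurements, got {bg.size}",
            stacklevel=2,
        )
    if bg.size == 0:
        raise ValueError("need at least one background measurement")
    return float(bg.mean() * snr)


def estimate_snr(
    image: np.ndarray,
    annotations: list[CellAnnotation],
    background_mean: float,
    top_fraction: float = 0.10,
) -> float:
    """Estimate SNR as top-decile annotated intensity over background mean."""
    if background_mean <= 0:
        raise ValueError("background mean must be > 0 to estimate SNR")
    union = np.zeros(image.shape, bool)
    for ann in annotations:
        union |= ann.mask
    vals = np.sort(np.asarray(image, float)[union])
    if vals.size == 0:
        raise ValueError("no annotated pixels")
    top = vals[int(np.floor((1 - top_fraction) * vals.size)):]
    return float(top.mean() / background_mean)


def fractional_area(
    annotation: CellAnnotation,
    target_image: np.ndarray,
    threshold: float,
    background_mean: float = np.nan,
    snr: float = np.nan,
) -> FractionalAreaResult:
    """Fraction of the annotated cell's pixels strictly above the threshold."""
    image = np.asarray(target_image, dtype=float)
    if annotation.mask.shape != image.shape:
        raise ValueError(
            f"annotation shape {annotation.mask.shape} does not match image {image.shape}"
        )
    inside = image[annotation.mask]
    fraction = float((inside > threshold).sum() / inside.size)
    return FractionalAreaResult(
        cell_id=annotation.cell_id,
        cell_type=annotation.cell_type,
        fraction=fraction,
        threshold=float(threshold),
        background_mean=float(background_mean),
        snr=float(snr),
        n_pixels=int(inside.size),
    )


def group_summary(results: pd.DataFrame, by: list[str] | None = None) -> dict:
    """Per-group mean ± s.e.m. of the fraction, plus the mean-ratio matrix.

    ``results`` is tidy with a ``fraction`` column and grouping columns
    (default ``["species", "cell_type"]``, falling back to whichever are
    present). Group labels are flattened to ``"level1/level2"`` strings.
    Returns ``{"groups": DataFrame(mean, sem, n), "ratios": DataFrame}``
    where ``ratios.loc[g1, g2] = mean(g1)/mean(g2)``. Empty groups simply
    do not appear; ratios against a zero mean are inf.
    """
    if by is None:
        by = [c for c in ("species", "cell_type") if c in results.columns]
    if not by:
        raise ValueError("no grouping columns found")
    grouped = results.groupby(by)["fraction"]
    stats = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "sem": grouped.sem(),
            "n": grouped.size(),
        }
    )
    stats.index = [
        "/".join(map(str, k)) if isinstance(k, tuple) else str(k)
        for k in stats.index
    ]
    names = list(stats.index)
    ratio = pd.DataFrame(index=names, columns=names, dtype=float)
    for g1, g2 in itertools.product(names, repeat=2):
        m1, m2 = stats.loc[g1, "mean"], stats.loc[g2, "mean"]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio.loc[g1, g2] = m1 / m2 if m2 != 0 else np.inf
    if (stats["n"] < MIN_CELLS_PER_REGION).any():
        warnings.warn(
            f"some groups have fewer than {MIN_CELLS_PER_REGION} cells",
            stacklevel=2,
        )
    return {"groups": stats, "ratios": ratio}


def annotations_from_geojson(
    payload: dict, shape: tuple[int, int]
) -> list[CellAnnotation]:
    """Build annotations from a GeoJSON FeatureCollection of cell polygons.

    Each feature must be a Polygon whose properties carry ``cell_type``
    (and optionally ``cell_id``). GeoJSON coordinates are (x, y) =
    (col, row); they are transposed to the (row, col) pixel convention.
    """
    anns = []
    for i, feat in enumerate(payload.get("features", [])):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(f"feature {i}: only Polygon geometries are supported")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        props = feat.get("properties", {})
        anns.append(
            CellAnnotation.from_polygon(
                vertices=ring[:, ::-1],  # (x, y) -> (row, col)
                shape=shape,
                cell_type=props.get("cell_type", "unknown"),
                cell_id=str(props.get("cell_id", f"cell-{i}")),
            )
        )
    return anns
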