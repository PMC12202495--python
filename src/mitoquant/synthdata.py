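"""Ground-truthed synthetic inputs: images, respirometry traces, TPM tables.

Every downstream stage of the pipeline is testable against known truth
without any external data. The generators emulate:

* multi-channel cortical z-stacks — a cell-marker channel bright inside
  known cell masks, a target channel carrying mitochondria-like disks of
  known calibrated area over autofluorescence background plus noise, and
  a nuclear channel;
* SUIT (substrate–uncoupler–inhibitor titration) oxygen traces that are
  piecewise linear with programmed per-state O2 flows between injections;
* two-group TPM expression tables with programmed signed fold changes
  and per-gene p-values.

Particle footprints are "exact-count discrete disks": the ``n`` pixels
closest to the center (ties broken in raster order), so the recorded
truth area equals the drawn pixel count × pixel_size² exactly.

All randomness flows through a single integer seed; identical spec + seed
give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import ROLES, LabeledStack
from .respirometry import SUIT_EVENT_ORDER, SUITExperiment

__all__ = [
    "ParticleSpec",
    "ImageTruth",
    "TraceTruth",
    "TableTruth",
    "disk_offsets",
    "generate_tissue_image",
    "generate_resp_trace",
    "generate_tpm_table",
    "random_image_truth",
    "write_stack",
    "read_stack",
    "write_truth_json",
]


# --------------------------------------------------------------------------
# image truth

@dataclass(frozen=True)
class ParticleSpec:
    """One programmed particle: center (row, col) px, area µm², placement flag."""

    center: tuple[int, int]
    area_um2: float
    inside_cell: bool = True


@dataclass
class ImageTruth:
    """Programmed content of a synthetic tissue image.

    ``cell_masks`` is an integer label image (one label per cell); the
    marker channel is rendered bright wherever a label is nonzero.
    Intensity units are arbitrary (a.u.); the paired defaults
    (background 100, amplitude 1000) give a punctate signal roughly an
    order of magnitude above background, typical of a well-exposed stain.
    """

    cell_masks: np.ndarray
    particles: list[ParticleSpec]
    pixel_size: float
    background_level: float = 100.0
    noise_sd: float = 0.0
    n_slices: int = 5
    slice_spacing: float = 1.0
    particle_amplitude: float = 1000.0
    marker_amplitude: float = 1000.0
    z_extent: tuple[int, int] | None = None  # contiguous slice run; None = all
    shot_noise: bool = False

    def __post_init__(self) -> None:
        self.cell_masks = np.asarray(self.cell_masks)
        if self.cell_masks.ndim != 2:
            raise ValueError("cell_masks must be a 2D label image")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for p in self.particles:
            if p.area_um2 <= 0:
                raise ValueError(f"particle area must be > 0, got {p.area_um2}")
        if self.z_extent is not None:
            lo, hi = self.z_extent
            if not (0 <= lo < hi <= self.n_slices):
                raise ValueError(f"z_extent {self.z_extent} outside 0..{self.n_slices}")


def disk_offsets(n_pixels: int) -> np.ndarray:
    """Offsets (dr, dc) of the discrete disk of exactly ``n_pixels`` pixels.

    Pixels are ranked by squared distance from the origin, ties broken in
    raster (row-major) order, and the first ``n_pixels`` taken. Deterministic.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    r = int(np.ceil(np.sqrt(n_pixels))) + 1
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dr**2 + dc**2
    order = np.lexsort((dc.ravel(), dr.ravel(), d2.ravel()))
    keep = order[:n_pixels]
    return np.stack([dr.ravel()[keep], dc.ravel()[keep]], axis=1)


def _render_particles(truth: ImageTruth) -> tuple[np.ndarray, list[ParticleSpec]]:
    """Paint particle disks onto a 2D canvas; return canvas and realized truth."""
    canvas = np.zeros(truth.cell_masks.shape, dtype=float)
    px2 = truth.pixel_size**2
    realized: list[ParticleSpec] = []
    rows, cols = canvas.shape
    for p in truth.particles:
        n_px = max(1, int(round(p.area_um2 / px2)))
        offs = disk_offsets(n_px)
        rr = offs[:, 0] + p.center[0]
        cc = offs[:, 1] + p.center[1]
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= rows or cc.max() >= cols:
            raise ValueError(
                f"particle at {p.center} (area {p.area_um2} µm²) extends outside "
                f"the {rows}x{cols} image"
            )
        canvas[rr, cc] = truth.particle_amplitude
        realized.append(replace(p, area_um2=n_px * px2))
    return canvas, realized


def generate_tissue_image(
    truth: ImageTruth, seed: int
) -> tuple[LabeledStack, ImageTruth]:
    """Render a 3-channel (marker, target, nuclear) z-stack from programmed truth.

    The returned truth is the realized one: each particle's area is the
    drawn pixel count × pixel_size² (identical to the requested area when
    it is an integer number of pixels).
    """
    rng = np.random.default_rng(seed)
    rows, cols = truth.cell_masks.shape
    shape3 = (truth.n_slices, rows, cols)

    marker2d = np.where(truth.cell_masks > 0, truth.marker_amplitude, 0.0)
    target2d, realized = _render_particles(truth)

    # nuclei: one small disk at each cell's centroid
    nuclear2d = np.zeros((rows, cols))
    for lab in np.unique(truth.cell_masks):
        if lab == 0:
            continue
        rs, cs = np.nonzero(truth.cell_masks == lab)
        cr, cc = int(rs.mean()), int(cs.mean())
        offs = disk_offsets(min(21, rs.size))
        rr = np.clip(offs[:, 0] + cr, 0, rows - 1)
        ccn = np.clip(offs[:, 1] + cc, 0, cols - 1)
        nuclear2d[rr, ccn] = truth.marker_amplitude

    lo, hi = truth.z_extent if truth.z_extent is not None else (0, truth.n_slices)
    channels = []
    for plane2d, in_z_run in ((marker2d, False), (target2d, True), (nuclear2d, False)):
        chan = np.full(shape3, truth.background_level, dtype=float)
        for z in range(truth.n_slices):
            if in_z_run and not (lo <= z < hi):
                continue
            chan[z] += plane2d
        channels.append(chan)
    voxels = np.stack(channels)

    if truth.shot_noise:
        voxels = rng.poisson(np.clip(voxels, 0, None)).astype(float)
    if truth.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, truth.noise_sd, size=voxels.shape)
    voxels = np.clip(voxels, 0.0, None)

    stack = LabeledStack(
        voxels=voxels,
        channel_roles={"marker": 0, "target": 1, "nuclear": 2},
        pixel_size=truth.pixel_size,
        slice_spacing=truth.slice_spacing,
        metadata={"synthetic": True, "seed": seed},
    )
    return stack, replace(truth, particles=realized)


#: default calibration for synthetic recovery studies: 0.1 µm² per pixel.
#: At this sampling the full programmed particle range (up to 2 µm² = 20 px)
#: stays below half the radius-4 median-filter footprint (≈ 25 px), the
#: regime where median background subtraction passes particles through
#: unchanged, and 0.3 / 0.4 µm² are exact pixel counts (3 / 4 px) so the
#: noise-cutoff boundary is representable exactly.
RECOVERY_PIXEL_SIZE = float(np.sqrt(0.1))


def random_image_truth(
    seed: int,
    shape: tuple[int, int] = (1024, 1024),
    n_inside: int = 100,
    n_outside: int = 0,
    area_range_um2: tuple[float, float] = (0.5, 2.0),
    pixel_size: float = RECOVERY_PIXEL_SIZE,
    min_spacing_diameters: float = 2.0,
    noise_sd: float = 0.0,
    sub_threshold: int = 0,
    sub_threshold_area_um2: float = 0.3,
    **kwargs,
) -> ImageTruth:
    """Place well-separated random disks inside (and optionally outside) a cell mask.

    The cell mask is a centered rectangle covering ~a third of the field;
    inside particles land within it, outside particles in the margin.
    Minimum center spacing is ``min_spacing_diameters`` × the largest
    particle diameter, so watershed never has to split programmed particles.
    ``sub_threshold`` adds extra disks below the usual 0.4 µm² noise cutoff.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    m_r, m_c = rows // 5, cols // 5
    cell = np.zeros(shape, dtype=np.int32)
    cell[m_r : rows - m_r, m_c : cols - m_c] = 1

    max_area = max(area_range_um2[1], sub_threshold_area_um2)
    r_max_px = np.sqrt(max_area / np.pi) / pixel_size
    min_dist = min_spacing_diameters * 2.0 * r_max_px
    pad = int(np.ceil(r_max_px)) + 2

    placed: list[tuple[int, int]] = []

    def _place(n: int, inside: bool) -> list[tuple[int, int]]:
        # keep the whole footprint on one side of the ROI edge, so no
        # programmed particle is clipped by the ROI restriction
        out: list[tuple[int, int]] = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 200 * n + 1000:
                raise RuntimeError("could not place particles with requested spacing")
            r = int(rng.integers(pad, rows - pad))
            c = int(rng.integers(pad, cols - pad))
            if inside:
                if not (m_r + pad <= r < rows - m_r - pad and m_c + pad <= c < cols - m_c - pad):
                    continue
            else:
                if (m_r - pad <= r < rows - m_r + pad) and (m_c - pad <= c < cols - m_c + pad):
                    continue
            if any((r - pr) ** 2 + (c - pc) ** 2 < min_dist**2 for pr, pc in placed):
                continue
            placed.append((r, c))
            out.append((r, c))
        return out

    particles = [
        ParticleSpec(center=ctr, area_um2=float(rng.uniform(*area_range_um2)), inside_cell=True)
        for ctr in _place(n_inside, inside=True)
    ]
    particles += [
        ParticleSpec(center=ctr, area_um2=float(rng.uniform(*area_range_um2)), inside_cell=False)
        for ctr in _place(n_outside, inside=False)
    ]
    particles += [
        ParticleSpec(center=ctr, area_um2=sub_threshold_area_um2, inside_cell=True)
        for ctr in _place(sub_threshold, inside=True)
    ]
    return ImageTruth(
        cell_masks=cell,
        particles=particles,
        pixel_size=pixel_size,
        noise_sd=noise_sd,
        **kwargs,
    )


# --------------------------------------------------------------------------
# respirometry truth

#: which programmed state drives the O2 slope after each injection
_SEGMENT_STATE_AFTER = {
    None: "Ce",          # before any injection
    "digitonin": "Ce",   # permeabilized, no substrate yet
    "pyruvate": "CI_L",  # partial substrate; generator uses leak flow
    "malate": "CI_L",
    "ADP": "CI_P",
    "cytc": "CIcytc",
    "succinate": "CIplusCII_P",
    "rotenone": "CII_P",
    "FCCP": "CII_E",
}


@dataclass
class TraceTruth:
    """Programmed content of a synthetic SUIT oxygen trace.

    ``state_flows`` maps state name → O2 flow in pmol·s⁻¹·(10⁶ cells)⁻¹;
    ``injection_times`` maps injection label → time (s) and must follow
    the SUIT order with strictly increasing times. ``cell_count`` is the
    chamber cell density in 10⁶ cells/mL; ``chamber_volume`` in mL.
    """

    state_flows: dict[str, float]
    injection_times: dict[str, float]
    cell_count: float = 0.55
    chamber_volume: float = 2.1
    noise_sd: float = 0.0
    o2_start: float = 200.0     # nmol/mL
    duration_s: float | None = None
    sample_interval_s: float = 2.0
    injection_artifact: float = 0.0  # instantaneous O2 jump at each injection, nmol/mL

    def __post_init__(self) -> None:
        for name, flow in self.state_flows.items():
            if flow < 0:
                raise ValueError(f"programmed flow for {name} must be >= 0, got {flow}")
        unknown = set(self.injection_times) - set(SUIT_EVENT_ORDER)
        if unknown:
            raise ValueError(f"unknown injection labels: {sorted(unknown)}")
        ordered = [e for e in SUIT_EVENT_ORDER if e in self.injection_times]
        times = [self.injection_times[e] for e in ordered]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("injection_times must be strictly increasing in SUIT order")
        if self.cell_count <= 0:
            raise ValueError("cell_count must be > 0")


def generate_resp_trace(
    truth: TraceTruth, seed: int
) -> tuple[SUITExperiment, TraceTruth]:
    """Synthesize a piecewise-linear O2 concentration trace from programmed flows.

    Between injections the concentration falls with slope
    −flow × cell_count / 1000 (nmol·mL⁻¹·s⁻¹), i.e. the slope a chamber at
    that cell density and per-cell flow would produce. Gaussian noise of
    ``noise_sd`` (flow units, propagated to concentration scale) is added
    pointwise; an optional re-oxygenation jump is applied at each injection.
    """
    rng = np.random.default_rng(seed)
    ordered = [e for e in SUIT_EVENT_ORDER if e in truth.injection_times]
    times = [truth.injection_times[e] for e in ordered]
    t_end = truth.duration_s
    if t_end is None:
        t_end = (times[-1] if times else 0.0) + 120.0

    t = np.arange(0.0, t_end + truth.sample_interval_s / 2, truth.sample_interval_s)
    breaks = [0.0] + times + [t_end]
    labels_after = [None] + ordered

    conc = np.empty_like(t)
    level = truth.o2_start
    for i, start_label in enumerate(labels_after):
        lo, hi = breaks[i], breaks[i + 1]
        state = _SEGMENT_STATE_AFTER[start_label]
        flow = truth.state_flows.get(state)
        if flow is None and state == "CIcytc":
            flow = truth.state_flows.get("CI_P", 0.0)
        flow = flow or 0.0
        slope = -flow * truth.cell_count / 1000.0
        seg = (t >= lo) & (t < hi) if hi < t_end else (t >= lo)
        conc[seg] = level + slope * (t[seg] - lo)
        level = level + slope * (hi - lo)
        if i < len(labels_after) - 1:
            level += truth.injection_artifact

    if truth.noise_sd > 0:
        conc = conc + rng.normal(0.0, truth.noise_sd * truth.cell_count / 1000.0, size=conc.shape)

    trace = pd.DataFrame({"time_s": t, "o2_conc": conc})
    events = pd.DataFrame(
        {"time_s": times, "label": ordered}
    )
    exp = SUITExperiment(
        trace=trace,
        events=events,
        cell_count=truth.cell_count,
        chamber_volume=truth.chamber_volume,
    )
    return exp, truth


# --------------------------------------------------------------------------
# expression truth

@dataclass
class TableTruth:
    """Programmed two-group TPM table: genes, group-A TPM, signed folds, p-values.

    Sign convention matches the pipeline's fold-change definition: a fold
    of +k means group B is k× group A; −k means group A is k× group B.
    A gene with ``tpm_a == 0`` and ``true_fold == 0`` is silent in both
    groups (exercises the TPM>0 expression filter).
    """

    genes: list[str]
    tpm_a: np.ndarray
    true_fold: np.ndarray
    pvals: np.ndarray

    def __post_init__(self) -> None:
        self.tpm_a = np.asarray(self.tpm_a, dtype=float)
        self.true_fold = np.asarray(self.true_fold, dtype=float)
        self.pvals = np.asarray(self.pvals, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names")
        n = len(self.genes)
        if not (self.tpm_a.shape == self.true_fold.shape == self.pvals.shape == (n,)):
            raise ValueError("genes, tpm_a, true_fold, pvals must have equal length")
        if (self.tpm_a < 0).any():
            raise ValueError("TPM must be >= 0")
        if ((self.pvals <= 0) | (self.pvals > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def tpm_b(self) -> np.ndarray:
        b = np.where(
            self.true_fold > 0,
            np.abs(self.true_fold) * self.tpm_a,
            np.divide(
                self.tpm_a,
                np.abs(self.true_fold),
                out=np.zeros_like(self.tpm_a),
                where=self.true_fold != 0,
            ),
        )
        return np.where(self.true_fold == 0, 0.0, b)


def generate_tpm_table(truth: TableTruth, seed: int) -> pd.DataFrame:
    """Materialize an expression table (gene, tpm_a, tpm_b, pval) honoring truth.

    Deterministic: programmed folds are honored exactly. ``seed`` is kept
    in the signature for interface symmetry with the other generators and
    fixes row order shuffling.
    """
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "gene": truth.genes,
            "tpm_a": truth.tpm_a,
            "tpm_b": truth.tpm_b,
            "pval": truth.pvals,
        }
    )
    return table.iloc[rng.permutation(len(table))].reset_index(drop=True)


# --------------------------------------------------------------------------
# plain-text I/O

def write_stack(stack: LabeledStack, tiff_path: str | Path) -> None:
    """Write a stack as multi-page 16-bit TIFF plus a YAML calibration sidecar.

    Page order is channel-major (all slices of channel 0, then channel 1, ...),
    documented in the sidecar. Intensities are clipped to the uint16 range.
    """
    tiff_path = Path(tiff_path)
    pages = np.clip(np.round(stack.voxels), 0, 65535).astype(np.uint16)
    n_chan, n_slices = pages.shape[:2]
    tifffile.imwrite(tiff_path, pages.reshape(-1, *pages.shape[2:]))
    sidecar = {
        "pixel_size_um": float(stack.pixel_size),
        "slice_spacing_um": float(stack.slice_spacing),
        "n_channels": int(n_chan),
        "n_slices": int(n_slices),
        "channel_roles": {k: int(v) for k, v in stack.channel_roles.items()},
        "page_order": "channel-major (channel, slice)",
    }
    tiff_path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_stack(tiff_path: str | Path) -> LabeledStack:
    """Read a stack written by :func:`write_stack` (TIFF + YAML sidecar)."""
    tiff_path = Path(tiff_path)
    meta = yaml.safe_load(tiff_path.with_suffix(".yaml").read_text())
    pages = tifffile.imread(tiff_path).astype(float)
    n_chan, n_slices = meta["n_channels"], meta["n_slices"]
    voxels = pages.reshape(n_chan, n_slices, *pages.shape[1:])
    return LabeledStack(
        voxels=voxels,
        channel_roles={k: int(v) for k, v in meta["channel_roles"].items() if k in ROLES},
        pixel_size=float(meta["pixel_size_um"]),
        slice_spacing=float(meta["slice_spacing_um"]),
    )


def write_truth_json(truth: ImageTruth, path: str | Path) -> None:
    """Serialize image truth (particles + scalars; masks as run-length counts)."""
    payload = {
        "pixel_size": truth.pixel_size,
        "background_level": truth.background_level,
        "noise_sd": truth.noise_sd,
        "n_slices": truth.n_slices,
        "slice_spacing": truth.slice_spacing,
        "n_cells": int(truth.cell_masks.max()),
        "particles": [
            {
                "center": list(p.center),
                "area_um2": p.area_um2,
                "inside_cell": bool(p.inside_cell),
            }
            for p in truth.particles
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
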