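"""Synapse and uptake morphometrics.

Quantities used to characterize efferocytic-synapse structure and
phagocytic/efferocytic capacity: Feret's diameter and its fold-change over
time (synapse expansion), Pearson colocalization between channels, radial
intensity profiles around the synapse centre, base-to-leading-edge cup
profiles normalized to a membrane reference, and the phagocytic /
efferocytic index (mean internalized targets per cell, with surface-bound
targets identified by an outside-only label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .synthetic import UptakeScene

__all__ = [
    "feret_diameter",
    "expansion_series",
    "pearson_colocalization",
    "radial_profile",
    "cup_profile",
    "uptake_index",
    "SynapseSeries",
    "CupProfile",
    "UptakeResult",
]


def _vertices(polygon) -> np.ndarray:
    if isinstance(polygon, Polygon):
        return np.asarray(polygon.exterior.coords)[:-1]
    arr = np.asarray(polygon, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("polygon needs at least three (x, y) vertices")
    return arr


def feret_diameter(polygon) -> float:
    """Maximum caliper (Feret's) diameter of a polygon, in its input units.

    Equals the maximum pairwise distance over convex-hull vertices.
    """
    pts = _vertices(polygon)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) input: brute force below
            pass
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return float(d.max())


@dataclass
class SynapseSeries:
    """Feret's-diameter time course of one synapse, normalized to onset."""

    times_min: np.ndarray
    feret_nm: np.ndarray
    fold_change: np.ndarray
    t0_index: int


def expansion_series(
    outlines: list,
    times_min: np.ndarray | None = None,
    min_area_nm2: float = 0.0,
) -> SynapseSeries:
    """Synapse expansion as fold-change of Feret's diameter over time.

    ``outlines`` holds one outer-edge polygon per time point (None when no
    synapse is visible).  Diameters are normalized to the first time point
    with a visible synapse — operationalized as the first outline whose area
    exceeds ``min_area_nm2`` (visibility in the source assays is a focal
    criterion that 2-D outlines cannot reproduce, hence the config floor).
    """
    if times_min is None:
        times_min = np.arange(len(outlines), dtype=float)
    times_min = np.asarray(times_min, dtype=float)
    feret = np.full(len(outlines), np.nan)
    visible = np.zeros(len(outlines), dtype=bool)
    for i, poly in enumerate(outlines):
        if poly is None:
            continue
        p = poly if isinstance(poly, Polygon) else Polygon(_vertices(poly))
        if p.area > min_area_nm2:
            feret[i] = feret_diameter(p)
            visible[i] = True
    if not visible.any():
        raise ValueError("no visible synapse at any time point")
    t0 = int(np.flatnonzero(visible)[0])
    return SynapseSeries(
        times_min=times_min,
        feret_nm=feret,
        fold_change=feret / feret[t0],
        t0_index=t0,
    )


def pearson_colocalization(
    img_a: np.ndarray, img_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation of two channels over masked pixels."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must share dimensions")
    if mask is not None:
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least two pixels")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant channel: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def radial_profile(
    image: np.ndarray,
    center_px: tuple[float, float],
    bin_width_px: float = 1.0,
    max_radius_px: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean intensity per concentric annulus about a centre point.

    Returns (bin centres, mean intensity, pixel counts).  Pixels are binned
    by centre distance, so the per-annulus means conserve the image total:
    sum(profile * counts) equals the image sum over covered pixels.
    """
    img = np.asarray(image, dtype=float)
    cx, cy = center_px
    if not (0 <= cx < img.shape[1] and 0 <= cy < img.shape[0]):
        raise ValueError("centre must lie inside the image")
    if bin_width_px < 1.0:
        raise ValueError("bin width below one pixel is not resolvable")
    yy, xx = np.indices(img.shape)
    r = np.hypot(xx - cx, yy - cy)
    if max_radius_px is None:
        max_radius_px = r.max()
    nbins = max(1, int(np.ceil(max_radius_px / bin_width_px)))
    idx = np.minimum((r / bin_width_px).astype(int), nbins)  # overflow bin
    counts = np.bincount(idx.ravel(), minlength=nbins + 1)[:nbins]
    sums = np.bincount(idx.ravel(), weights=img.ravel(), minlength=nbins + 1)[:nbins]
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = (np.arange(nbins) + 0.5) * bin_width_px
    return centres, means, counts


@dataclass
class CupProfile:
    """Base-to-leading-edge intensity profile through an efferocytic cup."""

    fractional_position: np.ndarray   # 0 = base, 1 = leading edge
    normalized_intensity: np.ndarray  # channel / membrane, min-max scaled
    engulfment_fraction: float
    flat: bool                        # True if the ratio had no dynamic range


def _profile_line(img: np.ndarray, start: tuple, end: tuple, n: int) -> np.ndarray:
    """Bilinear sample of ``img`` along the segment start->end ((x, y) px)."""
    from scipy.ndimage import map_coordinates
    xs = np.linspace(start[0], end[0], n)
    ys = np.linspace(start[1], end[1], n)
    return map_coordinates(img, np.vstack([ys, xs]), order=1)


def cup_profile(
    channel_img: np.ndarray,
    membrane_img: np.ndarray,
    base_px: tuple[float, float],
    tip_px: tuple[float, float],
    engulfment_fraction: float,
    engulfment_bounds: tuple[float, float] = (0.5, 0.75),
    n_samples: int = 100,
) -> CupProfile:
    """Normalized signal distribution through a cup, base to leading edge.

    The channel intensity is sampled along the cup axis, divided by the
    membrane-reference intensity (correcting for membrane density) and
    min–max scaled to [0, 1].  Cups outside the engulfment window (default
    50–75% of the target engulfed) are rejected: earlier cups have no
    leading edge, later ones no open rim.
    """
    lo, hi = engulfment_bounds
    if not lo <= engulfment_fraction <= hi:
        raise ValueError(
            f"cup at {engulfment_fraction:.0%} engulfment outside the "
            f"{lo:.0%}-{hi:.0%} analysis window"
        )
    ch = _profile_line(np.asarray(channel_img, float), base_px, tip_px, n_samples)
    mem = _profile_line(np.asarray(membrane_img, float), base_px, tip_px, n_samples)
    if np.any(mem <= 0):
        raise ValueError("membrane reference signal is zero along the profile")
    ratio = ch / mem
    rng = np.ptp(ratio)
    flat = bool(rng < 1e-12)
    scaled = np.full_like(ratio, 0.5) if flat else (ratio - ratio.min()) / rng
    return CupProfile(
        fractional_position=np.linspace(0.0, 1.0, n_samples),
        normalized_intensity=scaled,
        engulfment_fraction=engulfment_fraction,
        flat=flat,
    )


@dataclass
class UptakeResult:
    """Per-cell uptake counts (or normalized dye signal) and the group index."""

    per_cell_internalized: np.ndarray
    per_cell_bound: np.ndarray | None
    index: float                       # mean internalized per cell
    bound_per_cell: float | None
    mode: str


def _cell_masks(scene: UptakeScene) -> list[np.ndarray]:
    shape = scene.target_channel.shape
    masks = []
    for poly in scene.cell_polygons:
        verts = np.asarray(poly.exterior.coords)[:, ::-1] / scene.pixel_size_nm
        masks.append(polygon2mask(shape, verts))
    return masks


def uptake_index(
    scene: UptakeScene,
    mode: str = "beads",
    outside_overlap_threshold: float = 0.5,
    control_mean: float | None = None,
) -> UptakeResult:
    """Phagocytic/efferocytic index from a multi-channel uptake scene.

    beads mode — connected components of the target channel are assigned to
    the cell whose ROI contains their centroid; a bead is *bound* (not
    internalized) when at least ``outside_overlap_threshold`` of its
    footprint carries outside-label signal, since only non-internalized
    targets are accessible to the surface label.  The index is the mean
    internalized count per cell.

    apoptotic_cells mode — the outside-label channel is Otsu-thresholded,
    the mask inverted and applied to the tracer-dye channel; the integrated
    dye signal per cell ROI is the internalized amount, normalized to
    ``control_mean`` (the control-group mean) when given.
    """
    if not scene.cell_polygons:
        raise ValueError("scene has no cell ROIs")
    masks = _cell_masks(scene)

    if mode == "beads":
        lab = cc_label(scene.target_channel > 0)
        outside = scene.outside_channel > 0
        internal = np.zeros(len(masks))
        bound = np.zeros(len(masks))
        for region in regionprops(lab):
            rr, cc = region.coords[:, 0], region.coords[:, 1]
            cy, cx = region.centroid
            owner = next((i for i, m in enumerate(masks)
                          if m[int(round(cy)), int(round(cx))]), None)
            if owner is None:
                continue
            frac_outside = outside[rr, cc].mean()
            if frac_outside >= outside_overlap_threshold:
                bound[owner] += 1
            else:
                internal[owner] += 1
        return UptakeResult(
            per_cell_internalized=internal,
            per_cell_bound=bound,
            index=float(internal.mean()),
            bound_per_cell=float(bound.mean()),
            mode=mode,
        )

    if mode == "apoptotic_cells":
        if scene.dye_channel is None:
            raise ValueError("apoptotic_cells mode requires a dye channel")
        out_ch = scene.outside_channel
        if np.ptp(out_ch) == 0:
            inverted = np.ones_like(out_ch, dtype=bool)
        else:
            inverted = ~(out_ch > threshold_otsu(out_ch))
        dye = scene.dye_channel * inverted
        per_cell = np.array([float(dye[m].sum()) for m in masks])
        if control_mean is not None:
            if control_mean <= 0:
                raise ValueError("control mean must be positive")
            per_cell = per_cell / control_mean
        return UptakeResult(
            per_cell_internalized=per_cell,
            per_cell_bound=None,
            index=float(per_cell.mean()),
            bound_per_cell=None,
            mode=mode,
        )

    raise ValueError(f"unknown uptake mode: {mode!r}")
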