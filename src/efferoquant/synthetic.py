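"""Synthetic ground-truth data generators.

Every analysis stage in this package can be exercised on data produced here,
with the generating parameters returned as ground truth.  The generators
emulate the statistical structure of the corresponding experiments:

* two-species localization patterns (random, co-clustered, or contacting
  clusters) at membrane-receptor label densities,
* single-cluster stepwise-photobleaching intensity traces,
* three-channel (donor / transfer / acceptor) sensitized-emission FRET
  stacks with known bleed-through coefficients and a known true-efficiency
  map,
* 2-D Brownian / confined / directed trajectories with localization error,
* multi-cell uptake-assay scenes with known internalized / bound targets.

Conventions: continuous coordinates in nm, origin bottom-left, y up; frames
are 0-based; images are rasterized row-major with a stated nm/pixel and
pixel-centre convention.  All randomness flows from one seeded
``numpy.random.Generator`` per call — no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .fret import FretCoefficients, FretStack

__all__ = [
    "PatternSpec",
    "TraceSpec",
    "FretForwardSpec",
    "MotionSpec",
    "UptakeScene",
    "gen_point_pattern",
    "gen_bleach_trace",
    "gen_fret_stack",
    "gen_trajectories",
    "gen_uptake_scene",
]

#: Default localization precision (nm) for simulated SMLM patterns.  This is
#: a package default chosen to match ~20 nm-resolution localization data; it
#: is always echoed into the generated table's ``precision_nm`` column.
DEFAULT_PRECISION_NM = 20.0


# --------------------------------------------------------------------------
# point patterns
# --------------------------------------------------------------------------

@dataclass
class PatternSpec:
    """Two-species 2-D point-pattern specification.

    ``species_densities`` are molecules per µm² (the membrane-label regime is
    ~0.4/µm², i.e. one fluorophore per 2.5 µm²).  In ``coclustered`` mode both
    species share disk-shaped clusters of ``cluster_diameter_nm``; in
    ``contacting`` mode each species occupies its own disk and the two disks
    of a pair are separated edge-to-edge by ``contact_gap_nm``.
    """

    field_size_nm: float = 10_000.0
    mode: Literal["csr", "coclustered", "contacting"] = "csr"
    species_densities: dict[str, float] = field(
        default_factory=lambda: {"A": 0.4, "B": 0.4}
    )
    cluster_diameter_nm: float = 120.0
    cluster_occupancy: dict[str, int] = field(
        default_factory=lambda: {"A": 10, "B": 10}
    )
    contact_gap_nm: float = 0.0
    localization_precision_sd_nm: float = DEFAULT_PRECISION_NM
    n_clusters: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.field_size_nm <= 0:
            raise ValueError("field_size_nm must be positive")
        if any(d <= 0 for d in self.species_densities.values()):
            raise ValueError("species densities must be positive")
        if self.cluster_diameter_nm <= 0:
            raise ValueError("cluster_diameter_nm must be positive")
        if self.contact_gap_nm < 0:
            raise ValueError("contact_gap_nm must be non-negative")
        if self.localization_precision_sd_nm < 0:
            raise ValueError("localization_precision_sd_nm must be >= 0")
        if len(self.species_densities) != 2 and self.mode != "csr":
            raise ValueError("clustered modes require exactly two species")


def _pattern_n_clusters(spec: PatternSpec) -> int:
    if spec.n_clusters is not None:
        return int(spec.n_clusters)
    # implied by the first species' density and per-cluster occupancy
    area_um2 = (spec.field_size_nm / 1000.0) ** 2
    sp = next(iter(spec.species_densities))
    n = spec.species_densities[sp] * area_um2 / max(spec.cluster_occupancy[sp], 1)
    return max(1, int(round(n)))


def _uniform_in_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def gen_point_pattern(spec: PatternSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a two-species localization table plus ground truth.

    Returns
    -------
    table : DataFrame with columns ``id, frame, x_nm, y_nm, precision_nm,
        species``.
    truth : dict with keys ``mode``, ``cluster_centers`` (per species,
        (n, 2) nm arrays; empty for csr), ``cluster_id`` (per-point array,
        -1 for background) and the spec itself.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.field_size_nm
    area_um2 = (L / 1000.0) ** 2
    sd = spec.localization_precision_sd_nm

    rows: list[pd.DataFrame] = []
    centers: dict[str, np.ndarray] = {}
    cluster_ids: list[np.ndarray] = []

    if spec.mode == "csr":
        for sp, dens in spec.species_densities.items():
            n = rng.poisson(dens * area_um2)
            xy = rng.uniform(0.0, L, size=(n, 2))
            rows.append(pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1], "species": sp}))
            cluster_ids.append(np.full(n, -1))
            centers[sp] = np.empty((0, 2))
    else:
        n_clusters = _pattern_n_clusters(spec)
        radius = spec.cluster_diameter_nm / 2.0
        # keep disks fully inside the field so hull-based analyses see whole
        # clusters
        margin = radius + (spec.cluster_diameter_nm + spec.contact_gap_nm
                           if spec.mode == "contacting" else 0.0)
        margin = min(margin, L / 2.0 - 1.0)
        c0 = rng.uniform(margin, L - margin, size=(n_clusters, 2))
        sp_a, sp_b = list(spec.species_densities)
        if spec.mode == "coclustered":
            centers[sp_a] = c0
            centers[sp_b] = c0.copy()
        else:  # contacting: partner disk offset edge-to-edge by the gap
            th = rng.uniform(0.0, 2.0 * np.pi, size=n_clusters)
            offset = 2.0 * radius + spec.contact_gap_nm
            c1 = c0 + offset * np.column_stack([np.cos(th), np.sin(th)])
            centers[sp_a] = c0
            centers[sp_b] = c1
        for sp in (sp_a, sp_b):
            occ = int(spec.cluster_occupancy[sp])
            xy = np.concatenate([
                centers[sp][k] + _uniform_in_disk(rng, occ, radius)
                for k in range(n_clusters)
            ]) if occ > 0 else np.empty((0, 2))
            cid = np.repeat(np.arange(n_clusters), occ)
            rows.append(pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1], "species": sp}))
            cluster_ids.append(cid)

    table = pd.concat(rows, ignore_index=True)
    n_total = len(table)
    jitter = rng.normal(0.0, sd, size=(n_total, 2)) if sd > 0 else 0.0
    table[["x_nm", "y_nm"]] = table[["x_nm", "y_nm"]].to_numpy() + jitter
    table.insert(0, "id", np.arange(n_total))
    table.insert(1, "frame", np.zeros(n_total, dtype=int))
    table["precision_nm"] = sd if sd > 0 else 1e-3
    truth = {
        "mode": spec.mode,
        "cluster_centers": centers,
        "cluster_id": np.concatenate(cluster_ids) if cluster_ids else np.empty(0, int),
        "spec": spec,
    }
    return table, truth


def field_roi(spec: PatternSpec) -> Polygon:
    """The rectangular ROI covering a generated pattern's field."""
    L = spec.field_size_nm
    return Polygon([(0, 0), (L, 0), (L, L), (0, L)])


# --------------------------------------------------------------------------
# photobleaching traces
# --------------------------------------------------------------------------

@dataclass
class TraceSpec:
    """Single-cluster photobleaching trace specification.

    Each of ``n_steps`` fluorophores survives a geometric number of frames
    (per-frame bleaching probability ``bleach_rate``) and then bleaches
    irreversibly, so the noiseless trace is a monotone non-increasing
    staircase from ``baseline + n_steps*unit_intensity`` down to ``baseline``.
    """

    n_steps: int = 10
    unit_intensity: float = 100.0
    frame_interval_s: float = 0.1
    bleach_rate: float = 0.01
    noise_sd: float = 0.0
    baseline: float = 0.0
    tail_frames: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.unit_intensity <= 0:
            raise ValueError("unit_intensity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.bleach_rate < 1.0):
            raise ValueError("bleach_rate must be in (0, 1)")


def gen_bleach_trace(spec: TraceSpec) -> tuple[np.ndarray, dict]:
    """Generate an intensity trace and its ground-truth bleach schedule.

    Returns ``(intensity, truth)`` where ``truth['bleach_frames']`` holds the
    frame at which each fluorophore goes dark (sorted) and
    ``truth['n_active']`` the per-frame count of surviving fluorophores.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.n_steps == 0:
        n_frames = max(spec.tail_frames, 100)
        bleach_frames = np.empty(0, dtype=int)
    else:
        # geometric lifetime in frames (support 1, 2, ...): fluorophore is
        # bright during frames [0, life) and dark from frame `life` on
        lifetimes = rng.geometric(spec.bleach_rate, size=spec.n_steps)
        bleach_frames = np.sort(lifetimes)
        n_frames = int(bleach_frames[-1]) + spec.tail_frames
    t = np.arange(n_frames)
    n_active = spec.n_steps - np.searchsorted(bleach_frames, t, side="right")
    intensity = spec.baseline + spec.unit_intensity * n_active
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=n_frames)
    truth = {"bleach_frames": bleach_frames, "n_active": n_active, "spec": spec}
    return intensity.astype(float), truth


# --------------------------------------------------------------------------
# FRET forward model
# --------------------------------------------------------------------------

@dataclass
class FretForwardSpec:
    """Forward model for a three-channel sensitized-emission FRET stack.

    The forward model is, by construction, the exact algebraic inverse of
    :func:`efferoquant.fret.compute_ea` (documented side-by-side with it).
    With background- and noise-free signals, writing A for the acceptor
    abundance map and D for the donor abundance map::

        Iaa = A
        Idd = D * (1 - E) + alpha * A
        Ida = beta * D * (1 - E) + gamma * A + E * A

    so that F_c = Ida - beta*(Idd - alpha*Iaa) - gamma*Iaa = E*Iaa exactly,
    and E_A = F_c / Iaa = E.  It is an algebraic inverse, not a photophysics
    model: donor quenching is applied through E uniformly, and the sensitized
    term is expressed relative to the acceptor signal because E_A is the
    acceptor-normalized apparent efficiency.
    """

    true_e_map: np.ndarray = field(default_factory=lambda: np.zeros((64, 64)))
    donor_abundance: np.ndarray | float = 1000.0
    acceptor_abundance: np.ndarray | float = 1000.0
    coefficients: FretCoefficients = field(
        default_factory=lambda: FretCoefficients(alpha=0.05, beta=0.12, gamma=0.18)
    )
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        e = np.asarray(self.true_e_map, dtype=float)
        if np.any(e < 0) or np.any(e > 1):
            raise ValueError("true efficiency must lie in [0, 1]")
        for m in (self.donor_abundance, self.acceptor_abundance):
            if np.ndim(m) == 2 and np.shape(m) != e.shape:
                raise ValueError("abundance maps must match true_e_map shape")


def gen_fret_stack(spec: FretForwardSpec) -> FretStack:
    """Render Idd/Ida/Iaa images from a known true-efficiency map.

    Zeroing ``acceptor_abundance`` yields a donor-only control stack;
    zeroing ``donor_abundance`` an acceptor-only control (its true E is
    forced to 0 since FRET requires a donor).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    e = np.asarray(spec.true_e_map, dtype=float)
    d = np.broadcast_to(np.asarray(spec.donor_abundance, float), e.shape)
    a = np.broadcast_to(np.asarray(spec.acceptor_abundance, float), e.shape)
    if np.all(d == 0):
        e = np.zeros_like(e)
    c = spec.coefficients
    iaa = a.copy()
    idd = d * (1.0 - e) + c.alpha * a
    ida = c.beta * d * (1.0 - e) + c.gamma * a + e * a
    bg = spec.background
    channels = []
    for img, b in zip((idd, ida, iaa), bg):
        out = img + b
        if spec.noise_sd > 0:
            out = out + rng.normal(0.0, spec.noise_sd, size=e.shape)
        channels.append(out)
    return FretStack(Idd=channels[0], Ida=channels[1], Iaa=channels[2])


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass
class MotionSpec:
    """2-D motion model for simulated single-particle trajectories.

    ``brownian``: Gaussian increments with variance 2*D*dt per axis.
    ``confined``: the same increments with specular (billiard) reflection
    at a circular corral of ``corral_diameter_nm``.
    ``directed``: Brownian plus constant drift ``velocity_um_s``.
    Localization error is added to the true positions per frame.
    """

    model: Literal["brownian", "confined", "directed"] = "brownian"
    d_um2_s: float = 0.1
    corral_diameter_nm: float = 200.0
    velocity_um_s: float = 1.0
    n_tracks: int = 100
    track_length: int = 100
    frame_interval_s: float = 0.1
    localization_error_sd_nm: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.d_um2_s < 0:
            raise ValueError("D must be >= 0")
        if self.model == "confined":
            if self.corral_diameter_nm <= 0:
                raise ValueError("corral_diameter_nm must be positive")
            if self.corral_diameter_nm < 2 * self.localization_error_sd_nm:
                raise ValueError(
                    "corral smaller than twice the localization error is degenerate"
                )
        if self.n_tracks < 1 or self.track_length < 2:
            raise ValueError("need at least one track of length >= 2")


def _reflect_step(p0: np.ndarray, p1: np.ndarray, radius: float,
                  max_bounces: int = 100) -> np.ndarray:
    """Specular (billiard) reflection of straight steps at a circular wall.

    Each step from ``p0`` (inside) toward ``p1`` is reflected across the
    tangent at every boundary crossing until the endpoint lies inside.
    Billiard reflection preserves the uniform measure on the disk, so the
    stationary distribution of the confined walk is uniform — which is what
    makes the long-lag MSD plateau equal diameter²/4.
    """
    p0 = p0.copy()
    p1 = p1.copy()
    for _ in range(max_bounces):
        out = np.einsum("ij,ij->i", p1, p1) > radius ** 2
        if not np.any(out):
            break
        a, b = p0[out], p1[out]
        d = b - a
        dd = np.einsum("ij,ij->i", d, d)
        ad = np.einsum("ij,ij->i", a, d)
        aa = np.einsum("ij,ij->i", a, a)
        # first boundary crossing along the segment: |a + t d| = radius
        disc = np.sqrt(np.maximum(ad ** 2 - dd * (aa - radius ** 2), 0.0))
        t = (-ad + disc) / np.maximum(dd, 1e-300)
        hit = a + t[:, None] * d
        n = hit / radius
        rest = b - hit
        rest -= 2.0 * np.einsum("ij,ij->i", rest, n)[:, None] * n
        p0[out] = hit * (1.0 - 1e-12)   # nudge inside for the next pass
        p1[out] = p0[out] + rest
    return p1


def gen_trajectories(spec: MotionSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate trajectories; returns (table, truth).

    Table columns: ``id, frame, x_nm, y_nm, precision_nm``.  Truth carries
    the noise-free positions and the generating spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_interval_s
    d_nm2_s = spec.d_um2_s * 1e6  # µm²/s -> nm²/s
    step_sd = np.sqrt(2.0 * d_nm2_s * dt)
    n, L = spec.n_tracks, spec.track_length
    radius = spec.corral_diameter_nm / 2.0

    steps = rng.normal(0.0, step_sd, size=(n, L - 1, 2)) if step_sd > 0 else np.zeros((n, L - 1, 2))
    if spec.model == "directed":
        drift_nm = spec.velocity_um_s * 1e3 * dt
        theta = rng.uniform(0.0, 2 * np.pi, size=n)
        steps += drift_nm * np.stack([np.cos(theta), np.sin(theta)], axis=-1)[:, None, :]

    if spec.model == "confined":
        pos = np.zeros((n, L, 2))
        pos[:, 0] = _uniform_in_disk(rng, n, radius)
        for k in range(1, L):
            pos[:, k] = _reflect_step(pos[:, k - 1],
                                      pos[:, k - 1] + steps[:, k - 1], radius)
        # per-track random corral centre somewhere in a 10x10 µm field
        centres = rng.uniform(radius, 10_000 - radius, size=(n, 1, 2))
        pos = pos + centres
    else:
        origin = rng.uniform(0.0, 10_000.0, size=(n, 1, 2))
        pos = origin + np.concatenate(
            [np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1
        )

    err_sd = spec.localization_error_sd_nm
    obs = pos + rng.normal(0.0, err_sd, size=pos.shape) if err_sd > 0 else pos.copy()

    table = pd.DataFrame({
        "id": np.repeat(np.arange(n), L),
        "frame": np.tile(np.arange(L), n),
        "x_nm": obs[:, :, 0].ravel(),
        "y_nm": obs[:, :, 1].ravel(),
        "precision_nm": max(err_sd, 1e-3),
    })
    truth = {"true_positions": pos, "spec": spec}
    return table, truth


# --------------------------------------------------------------------------
# uptake scenes
# --------------------------------------------------------------------------

@dataclass
class UptakeScene:
    """A rasterized multi-cell uptake-assay scene plus vector ground truth.

    ``target_channel`` carries all targets (beads or apoptotic cells);
    ``outside_channel`` marks only non-internalized targets, emulating
    surface labeling of whatever remains accessible from the medium
    (anti-IgG for beads, streptavidin for biotinylated targets);
    ``dye_channel`` (apoptotic-cell mode) carries the tracer dye of every
    target, internalized or not.
    """

    cell_polygons: list[Polygon]
    target_channel: np.ndarray
    outside_channel: np.ndarray
    dye_channel: np.ndarray | None
    pixel_size_nm: float
    truth: dict


def _place_disks(rng, centre, cell_r, n, disk_r, existing):
    pts = []
    while len(pts) < n:
        off = _uniform_in_disk(rng, 1, cell_r - disk_r - 2)[0]
        p = centre + off
        if all(np.hypot(*(p - q)) > 2 * disk_r + 1 for q in existing + pts):
            pts.append(p)
    return pts


def gen_uptake_scene(
    n_cells: int,
    beads_internal_per_cell: int,
    beads_external_per_cell: int,
    seed: int = 0,
    mode: Literal["beads", "apoptotic_cells"] = "beads",
    dye_intensity: float = 100.0,
    pixel_size_nm: float = 200.0,
) -> UptakeScene:
    """Build a synthetic scene of phagocytes with bound and engulfed targets.

    Cells are disks laid out on a grid; each contains
    ``beads_internal_per_cell`` internalized and ``beads_external_per_cell``
    surface-bound targets.  Ground truth (per-cell counts, target centres,
    per-target masks, expected index) is attached for exact verification.
    """
    if min(n_cells, beads_internal_per_cell, beads_external_per_cell) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    tile = 100  # px per cell tile
    cell_r = 40.0
    bead_r = 4.0
    ncol = max(1, int(np.ceil(np.sqrt(max(n_cells, 1)))))
    nrow = max(1, int(np.ceil(max(n_cells, 1) / ncol)))
    H, W = nrow * tile, ncol * tile
    target = np.zeros((H, W))
    outside = np.zeros((H, W))
    dye = np.zeros((H, W))
    yy, xx = np.mgrid[0:H, 0:W]

    polys, per_cell = [], []
    for i in range(n_cells):
        r_, c_ = divmod(i, ncol)
        centre = np.array([c_ * tile + tile / 2, r_ * tile + tile / 2])  # (x, y)
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        polys.append(Polygon(np.column_stack([
            centre[0] + cell_r * np.cos(th), centre[1] + cell_r * np.sin(th)
        ]) * pixel_size_nm))
        placed: list[np.ndarray] = []
        internal = _place_disks(rng, centre, cell_r, beads_internal_per_cell, bead_r, placed)
        placed += internal
        external = _place_disks(rng, centre, cell_r, beads_external_per_cell, bead_r, placed)
        for p in internal + external:
            disk = (xx - p[0]) ** 2 + (yy - p[1]) ** 2 <= bead_r ** 2
            target[disk] = 255.0
            dye[disk] = dye_intensity
        for p in external:
            disk = (xx - p[0]) ** 2 + (yy - p[1]) ** 2 <= bead_r ** 2
            outside[disk] = 255.0
        per_cell.append({
            "internal_centers_px": np.array(internal).reshape(-1, 2),
            "external_centers_px": np.array(external).reshape(-1, 2),
            "n_internal": beads_internal_per_cell,
            "n_external": beads_external_per_cell,
        })

    n_int_px = np.pi * bead_r ** 2  # approximate; exact value in truth
    truth = {
        "per_cell": per_cell,
        "index": float(beads_internal_per_cell),
        "bound": float(beads_external_per_cell),
        "dye_intensity": dye_intensity,
        "internal_dye_integral_per_cell": [
            float(dye_intensity) * _disk_pixel_count(c["internal_centers_px"], bead_r, H, W)
            for c in per_cell
        ],
        "bead_radius_px": bead_r,
        "approx_bead_area_px": n_int_px,
    }
    return UptakeScene(
        cell_polygons=polys,
        target_channel=target,
        outside_channel=outside,
        dye_channel=dye if mode == "apoptotic_cells" else None,
        pixel_size_nm=pixel_size_nm,
        truth=truth,
    )


def _disk_pixel_count(centers: np.ndarray, r: float, H: int, W: int) -> int:
    if len(centers) == 0:
        return 0
    yy, xx = np.mgrid[0:H, 0:W]
    m = np.zeros((H, W), bool)
    for p in centers:
        m |= (xx - p[0]) ** 2 + (yy - p[1]) ** 2 <= r ** 2
    return int(m.sum())
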