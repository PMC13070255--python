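"""Corrected sensitized-emission FRET for integrin conformational readout.

The assay reads β₂-integrin activation as FRET between a FITC-labeled
head-group antibody (donor) and octadecyl-rhodamine B in the plasma membrane
(acceptor): the bent, inactive integrin holds the head group near the
membrane and FRETs strongly; extension on activation moves the head group
away and *decreases* E_A.  Three channels are acquired — donor
excitation/donor emission (Idd), donor excitation/acceptor emission (Ida,
the raw FRET channel) and acceptor excitation/acceptor emission (Iaa) — and
the sensitized emission is isolated by subtracting bleed-through measured on
single-label controls:

* beta  — donor cross-talk, Ida/Idd on donor-only cells
* alpha — acceptor cross-excitation into the donor channel, Idd/Iaa on
  acceptor-only cells
* gamma — acceptor cross-excitation, Ida/Iaa on acceptor-only cells
* delta — FRET cross-talk, Idd/Ida on acceptor-only cells (measured for QC;
  by its definition it equals alpha/gamma and carries no independent
  information, so it does not enter the E_A formula)

The corrected sensitized emission and apparent efficiency are::

    F_c = Ida - beta*(Idd - alpha*Iaa) - gamma*Iaa
    E_A = F_c / Iaa        (clamped to [0, E_MAX])

with all channels background-subtracted first.  E_MAX = 0.3136, the maximum
theoretical efficiency of the FITC/ORB pair, is used as a clamp constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.morphology import dilation

__all__ = [
    "E_MAX",
    "FretStack",
    "FretCoefficients",
    "FretMap",
    "estimate_coefficients",
    "compute_ea",
    "build_mask",
    "roi_fret",
    "activation_display",
]

#: Maximum theoretical FRET efficiency of the FITC / octadecyl-rhodamine B
#: pair; used as a clamp, not recomputed.
E_MAX = 0.3136


@dataclass
class FretStack:
    """Registered three-channel acquisition (donor, FRET, acceptor)."""

    Idd: np.ndarray
    Ida: np.ndarray
    Iaa: np.ndarray
    dic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Idd = np.asarray(self.Idd, dtype=float)
        self.Ida = np.asarray(self.Ida, dtype=float)
        self.Iaa = np.asarray(self.Iaa, dtype=float)
        if not (self.Idd.shape == self.Ida.shape == self.Iaa.shape):
            raise ValueError("FRET channels must share dimensions")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.Idd.shape


@dataclass
class FretCoefficients:
    """Bleed-through coefficients and per-channel backgrounds.

    ``background`` and ``background_sd`` are (Idd, Ida, Iaa) tuples, median
    and robust sd of unstained-cell pixels.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float | None = None
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FretMap:
    """Pixelwise apparent FRET efficiency with its validity mask."""

    E_A: np.ndarray          # NaN where undefined
    defined: np.ndarray      # True where E_A is defined
    mask: np.ndarray | None = None  # Otsu AND mask, if applied
    e_max: float = E_MAX


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def estimate_coefficients(
    donor_only: FretStack,
    acceptor_only: FretStack,
    unstained: FretStack,
    signal_sd_factor: float = 3.0,
) -> FretCoefficients:
    """Estimate bleed-through coefficients from single-label control stacks.

    Backgrounds are per-channel medians of the unstained stack.  Each
    coefficient is the median of the defining channel ratio over control
    pixels whose denominator channel exceeds background by
    ``signal_sd_factor`` robust sds (median-of-ratios is insensitive to the
    bright debris that plagues mean-based estimates).
    """
    bg = tuple(float(np.median(ch)) for ch in (unstained.Idd, unstained.Ida, unstained.Iaa))
    bg_sd = tuple(_robust_sd(ch) for ch in (unstained.Idd, unstained.Ida, unstained.Iaa))

    def ratio(num: np.ndarray, num_bg: float, den: np.ndarray, den_bg: float,
              den_sd: float) -> float:
        d = den - den_bg
        sel = d > signal_sd_factor * max(den_sd, 1e-12)
        if not np.any(sel):
            raise ValueError("control stack has no above-background pixels")
        return float(np.median((num[sel] - num_bg) / d[sel]))

    beta = ratio(donor_only.Ida, bg[1], donor_only.Idd, bg[0], bg_sd[0])
    alpha = ratio(acceptor_only.Idd, bg[0], acceptor_only.Iaa, bg[2], bg_sd[2])
    gamma = ratio(acceptor_only.Ida, bg[1], acceptor_only.Iaa, bg[2], bg_sd[2])
    delta = ratio(acceptor_only.Idd, bg[0], acceptor_only.Ida, bg[1], bg_sd[1])
    coeffs = FretCoefficients(alpha=alpha, beta=beta, gamma=gamma, delta=delta,
                              background=bg, background_sd=bg_sd)
    coeffs.validate()
    return coeffs


def compute_ea(
    stack: FretStack,
    coeffs: FretCoefficients,
    e_max: float = E_MAX,
    iaa_floor: float | None = None,
    background_subtracted: bool = False,
    clamp: bool = True,
) -> FretMap:
    """Pixelwise apparent FRET efficiency E_A = F_c / Iaa.

    Backgrounds from ``coeffs`` are subtracted (unless the stack already is)
    and the channels clamped at zero.  Pixels whose acceptor signal falls
    below ``iaa_floor`` (default 3x the acceptor background sd) are undefined
    — the division is meaningless there.  Defined values are clamped to
    ``[0, e_max]`` by default; pass ``clamp=False`` when *averaging* E_A
    over a region, because folding the per-pixel noise at the physical
    bounds biases the regional mean (the clamped map is for display and
    validity screening).
    """
    coeffs.validate()
    if background_subtracted:
        idd, ida, iaa = stack.Idd, stack.Ida, stack.Iaa
    else:
        idd = np.clip(stack.Idd - coeffs.background[0], 0.0, None)
        ida = np.clip(stack.Ida - coeffs.background[1], 0.0, None)
        iaa = np.clip(stack.Iaa - coeffs.background[2], 0.0, None)
    if iaa_floor is None:
        iaa_floor = 3.0 * coeffs.background_sd[2]
    iaa_floor = max(iaa_floor, 1e-12)

    fc = ida - coeffs.beta * (idd - coeffs.alpha * iaa) - coeffs.gamma * iaa
    defined = iaa > iaa_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ea = np.where(defined, fc / np.where(defined, iaa, 1.0), np.nan)
    if clamp:
        ea = np.where(defined, np.clip(ea, 0.0, e_max), np.nan)
    return FretMap(E_A=ea, defined=defined, e_max=e_max)


def build_mask(iaa: np.ndarray, idd: np.ndarray) -> np.ndarray:
    """Otsu threshold each channel, AND the masks, dilate once (3x3).

    Restricts the E_A map to pixels carrying both acceptor (membrane) and
    donor (integrin) signal, suppressing spurious ratios elsewhere.
    """
    iaa = np.asarray(iaa, float)
    idd = np.asarray(idd, float)
    if iaa.shape != idd.shape:
        raise ValueError("channels must share dimensions")
    masks = []
    for ch in (iaa, idd):
        if np.ptp(ch) == 0:
            raise ValueError("constant channel: Otsu threshold undefined")
        masks.append(ch > threshold_otsu(ch))
    combined = masks[0] & masks[1]
    return dilation(combined, np.ones((3, 3), bool)).astype(bool)


def apply_mask(fret_map: FretMap, mask: np.ndarray) -> FretMap:
    """Return a copy of the map restricted to ``mask`` pixels."""
    defined = fret_map.defined & mask
    ea = np.where(defined, fret_map.E_A, np.nan)
    return FretMap(E_A=ea, defined=defined, mask=mask, e_max=fret_map.e_max)


def roi_fret(
    fret_map: FretMap,
    roi: Polygon,
    pixel_size_nm: float = 1.0,
) -> dict:
    """Mean E_A over defined (and masked, if set) pixels inside an ROI.

    The ROI polygon is in nm; pixel centres falling inside it are selected.
    Returns mean, pixel count and the value distribution.
    """
    shape = fret_map.E_A.shape
    # polygon2mask takes (row, col) vertices; our polygons are (x, y) nm
    verts_px = np.array([(y / pixel_size_nm, x / pixel_size_nm)
                         for x, y in np.asarray(roi.exterior.coords)])
    roi_mask = polygon2mask(shape, verts_px)
    sel = roi_mask & fret_map.defined
    if fret_map.mask is not None:
        sel &= fret_map.mask
    if not np.any(sel):
        raise ValueError("ROI does not intersect the defined FRET mask")
    values = fret_map.E_A[sel]
    return {
        "mean_ea": float(np.mean(values)),
        "median_ea": float(np.median(values)),
        "n_pixels": int(sel.sum()),
        "values": values,
    }


def activation_display(fret_map: FretMap) -> np.ndarray:
    """16-bit display image with inverted polarity: high = activation.

    Activation extends the integrin and moves the donor away from the
    membrane acceptor, so activation corresponds to *low* E_A; the display
    map is therefore monotone decreasing in E_A.  Undefined pixels map to 0.
    """
    ea = np.where(fret_map.defined, fret_map.E_A, fret_map.e_max)
    out = (fret_map.e_max - ea) / fret_map.e_max * np.iinfo(np.uint16).max
    return out.astype(np.uint16)
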