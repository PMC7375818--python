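"""Cavalieri point counting and shrinkage/artifact correction arithmetic.

Volume fractions (V_v) of tissue compartments are estimated by overlaying
a square point grid of known area-per-point on label images and counting
hits per class; the fraction of a stack occupied by fixation artifacts is
estimated the same way on regularly spaced sections.  Linear, areal and
volumetric measurements made on processed (shrunken) tissue are restored
to pre-processing scale with the factors p^2 (in-plane area), p (in-plane
length) and p_z (section thickness); densities are additionally corrected
for the artifact volume discounted from each stack.
"""

from __future__ import annotations

import decimal
import math
import warnings
from dataclasses import dataclass, field

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report style)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class GridSpec:
    """Square stereological point grid.

    ``area_per_point`` is the tissue area associated with each grid
    point (e.g. 400 um^2 on semithin sections, 400,000 nm^2 on FIB/SEM
    sections); the point spacing is its square root.  ``origin`` offsets
    the first point from the image corner, in the same length unit.
    """

    area_per_point: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.area_per_point <= 0:
            raise ValueError("area_per_point must be positive")

    @property
    def spacing(self) -> float:
        return math.sqrt(self.area_per_point)


@dataclass(frozen=True)
class ShrinkageFactors:
    """Processed-to-fresh tissue scale factors.

    ``p2`` is the in-plane area factor, ``p = sqrt(p2)`` the in-plane
    linear factor, ``pz`` the section-thickness factor and
    ``s_vol = p2 * pz`` the volume factor.  Factors of 1 mean no
    shrinkage; values above 1 (swelling) are accepted with a warning at
    construction from raw measurements.
    """

    p2: float
    pz: float
    p: float = field(init=False)
    s_vol: float = field(init=False)

    def __post_init__(self) -> None:
        if self.p2 <= 0 or self.pz <= 0:
            raise ValueError("shrinkage factors must be positive")
        object.__setattr__(self, "p", math.sqrt(self.p2))
        object.__setattr__(self, "s_vol", self.p2 * self.pz)

    @classmethod
    def identity(cls) -> "ShrinkageFactors":
        return cls(p2=1.0, pz=1.0)


#: Factors measured in the CA1 study conditions: p^2 = 0.933, p_z = 0.901.
STUDY_FACTORS = ShrinkageFactors(p2=0.933, pz=0.901)


def shrinkage_factors(
    pre_area: float, post_area: float,
    pre_thickness: float, post_thickness: float,
) -> ShrinkageFactors:
    """Compute shrinkage factors from pre/post processing measurements.

    ``p2 = post_area / pre_area``; ``pz = post_thickness / pre_thickness``.
    """
    vals = (pre_area, post_area, pre_thickness, post_thickness)
    if any(v <= 0 for v in vals):
        raise ValueError("all pre/post measurements must be positive")
    if post_area > pre_area or post_thickness > pre_thickness:
        warnings.warn("post-processing measurement exceeds pre-processing "
                      "(tissue swelling); factor computed anyway")
    return ShrinkageFactors(p2=post_area / pre_area,
                            pz=post_thickness / pre_thickness)


@dataclass(frozen=True)
class VvEstimate:
    """Cavalieri volume-fraction estimate from point counts."""

    counts: dict[str, int]
    total_points: int
    vv_percent: dict[str, float]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("point counts must be nonnegative")
        s = sum(self.vv_percent.values())
        if abs(s - 100.0) > 1e-9:
            raise ValueError(f"V_v values sum to {s}, not 100")


def _grid_hits(image: np.ndarray, grid: GridSpec, pixel_size: float) -> np.ndarray:
    """Labels under each grid point (points on boundaries take floor)."""
    if image.ndim != 2 or image.size == 0:
        raise ValueError("label image must be a nonempty 2D array")
    ny, nx = image.shape
    sp = grid.spacing
    oy, ox = grid.origin[1], grid.origin[0]
    xs = np.arange(ox, nx * pixel_size, sp)
    ys = np.arange(oy, ny * pixel_size, sp)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("grid spacing larger than image extent")
    ix = np.floor(xs / pixel_size).astype(int)
    iy = np.floor(ys / pixel_size).astype(int)
    return image[np.ix_(iy, ix)].ravel()


def cavalieri_vv(
    label_image: np.ndarray,
    grid: GridSpec,
    pixel_size: float = 1.0,
    class_names: dict[int, str] | None = None,
    remainder_class: str | None = None,
) -> VvEstimate:
    """Estimate volume fractions on a 2D label image by point counting.

    Each grid point takes the label of the pixel under it; V_v of a
    class is its hit share in percent.  If ``remainder_class`` is given
    (the neuropil convention) its V_v is reported as 100 minus the sum
    of the explicitly counted classes.

    ``pixel_size`` converts grid coordinates (same unit as the grid's
    ``area_per_point``) to pixels.
    """
    hits = _grid_hits(np.asarray(label_image), grid, pixel_size)
    total = int(hits.size)
    labels, counts = np.unique(hits, return_counts=True)
    name_of = class_names or {int(l): str(int(l)) for l in labels}
    count_map = {name_of.get(int(l), str(int(l))): int(c)
                 for l, c in zip(labels, counts)}
    vv = {name: 100.0 * c / total for name, c in count_map.items()}
    if remainder_class is not None:
        others = {k: v for k, v in vv.items() if k != remainder_class}
        vv = dict(others)
        vv[remainder_class] = 100.0 - sum(others.values())
        count_map.setdefault(remainder_class, total - sum(others_c for k, others_c
                             in count_map.items() if k != remainder_class))
    return VvEstimate(counts=count_map, total_points=total, vv_percent=vv)


def estimate_artifact_fraction(
    mask: np.ndarray,
    grid: GridSpec,
    pixel_size: float = 1.0,
    section_step: int = 20,
) -> float:
    """Point-count the artifact share of a binary stack mask.

    Counting is done on every ``section_step``-th section (first axis);
    if the step exceeds the stack depth, the single middle section is
    used, with a warning.  Returns the occupied fraction in [0, 1].
    """
    mask = np.asarray(mask)
    if mask.ndim != 3 or mask.shape[0] < 1:
        raise ValueError("mask must be a 3D array with >= 1 section")
    if section_step < 1:
        raise ValueError("section_step must be >= 1")
    if section_step > mask.shape[0]:
        warnings.warn("section step exceeds stack depth; "
                      "sampling the middle section only")
        planes = [mask.shape[0] // 2]
    else:
        planes = list(range(0, mask.shape[0], section_step))
    hit = tot = 0
    for z in planes:
        h = _grid_hits(mask[z], grid, pixel_size)
        hit += int((h > 0).sum())
        tot += h.size
    return hit / tot


_CORRECTION_KINDS = ("length", "area", "volume", "density")


def apply_correction(
    value: float,
    kind: str,
    factors: ShrinkageFactors,
    artifact_fraction: float = 0.0,
) -> float:
    """Restore a processed-tissue measurement to pre-processing scale.

    * ``length``: divide by p (in-plane linear factor).
    * ``area``: divide by p^2.
    * ``volume``: discount the artifact share measured in the processed
      stack, then divide by the volume factor:
      ``value * (1 - artifact_fraction) / s_vol``.
    * ``density``: a count-per-volume recomputed against the corrected
      volume: ``value * s_vol / (1 - artifact_fraction)``.
    """
    if kind not in _CORRECTION_KINDS:
        raise ValueError(f"unknown correction kind {kind!r}; "
                         f"expected one of {_CORRECTION_KINDS}")
    if value < 0:
        raise ValueError("value must be nonnegative")
    if not (0.0 <= artifact_fraction < 1.0):
        raise ValueError("artifact_fraction must lie in [0, 1)")
    if kind == "length":
        return value / factors.p
    if kind == "area":
        return value / factors.p2
    if kind == "volume":
        return value * (1.0 - artifact_fraction) / factors.s_vol
    return value * factors.s_vol / (1.0 - artifact_fraction)
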