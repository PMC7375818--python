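"""Unbiased 3D counting frame and synaptic-density estimation.

A counting frame (the 3D "brick" rule) partitions the six faces of an
inner sampling box into three inclusion faces and three exclusion faces
so that every particle is countable in exactly one frame position.  Here
the exclusion faces are the minimum-x/y/z faces and the inclusion faces
the maxima.  With only centroids available (the default synapse-table
case) the rule degrades to centroid-in-box with open boundaries on the
exclusion faces: a centroid exactly on an exclusion face is discarded,
one on an inclusion face is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stereology import ShrinkageFactors, round_half_up
from .synthgen import NM3_PER_UM3, StackGeometry

_COORDS = ("cx_nm", "cy_nm", "cz_nm")


@dataclass(frozen=True)
class CountingFrame:
    """Inner sampling box in nm with fixed inclusion/exclusion faces.

    ``lo``/``hi`` are the minimum and maximum corners.  Exclusion faces
    sit at ``lo`` (open boundaries), inclusion faces at ``hi`` (closed).
    """

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lo, float), np.asarray(self.hi, float)
        if not (hi > lo).all():
            raise ValueError("counting frame must have positive extent")

    @classmethod
    def from_stack(cls, geom: StackGeometry, margin: float) -> "CountingFrame":
        """Frame inset by ``margin`` nm from every stack face."""
        ext = geom.extents
        if margin < 0 or (2 * margin >= ext).any():
            raise ValueError("margin must be nonnegative and leave a nonempty box")
        return cls(tuple(np.full(3, margin)), tuple(ext - margin))

    @property
    def volume_um3(self) -> float:
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        return float(np.prod(hi - lo)) / NM3_PER_UM3

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Centroid brick rule: lo < p <= hi on every axis."""
        p = np.atleast_2d(np.asarray(points, float))
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        return ((p > lo) & (p <= hi)).all(axis=1)


def counting_frame_filter(
    records: pd.DataFrame,
    frame: CountingFrame,
    stack: StackGeometry | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Keep the records countable in the frame (centroid brick rule).

    Returns the included subset and a sidecar dict recording the frame
    geometry, the rule applied, and the inclusion decisions, suitable
    for JSON serialization next to the output table.
    """
    if stack is not None:
        lo, hi = np.asarray(frame.lo), np.asarray(frame.hi)
        if (lo < 0).any() or (hi > stack.extents).any():
            raise ValueError("counting frame extends outside the stack")
    pts = records[list(_COORDS)].to_numpy(float)
    keep = frame.contains(pts) if len(records) else np.zeros(0, bool)
    meta = {
        "rule": "centroid_in_box",
        "note": ("full-extent intersection rule unavailable without meshes; "
                 "centroid fallback with open exclusion-face boundaries"),
        "exclusion_faces": ["min_x", "min_y", "min_z"],
        "inclusion_faces": ["max_x", "max_y", "max_z"],
        "frame_lo_nm": list(map(float, frame.lo)),
        "frame_hi_nm": list(map(float, frame.hi)),
        "n_input": int(len(records)),
        "n_included": int(keep.sum()),
        "included_ids": records.loc[keep, "id"].tolist() if "id" in records else None,
    }
    return records.loc[keep].copy(), meta


@dataclass(frozen=True)
class DensityEstimate:
    """Synapse count per counting-frame volume."""

    n_included: int
    cf_volume_um3: float
    density_per_um3: float
    corrected: bool

    def __post_init__(self) -> None:
        if self.n_included < 0 or self.cf_volume_um3 <= 0:
            raise ValueError("count must be nonnegative and volume positive")
        if abs(self.density_per_um3 * self.cf_volume_um3 - self.n_included) > \
                1e-9 * max(1.0, self.n_included):
            raise ValueError("density inconsistent with count/volume")

    @property
    def density_2dp(self) -> float:
        """Report-style density, rounded half-up to 2 decimals."""
        return round_half_up(self.density_per_um3, 2)


def synaptic_density(
    n: int,
    volume_um3: float,
    factors: ShrinkageFactors | None = None,
    artifact_fraction: float = 0.0,
) -> DensityEstimate:
    """Synapses per um^3 against the (optionally corrected) CF volume.

    With ``factors`` given, the raw volume is first discounted by the
    stack's artifact fraction and then restored to pre-processing scale
    (divided by the volume shrinkage factor); otherwise the raw volume
    is used as-is.
    """
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    if n < 0:
        raise ValueError("count must be nonnegative")
    corrected = factors is not None
    vol = volume_um3
    if corrected:
        if not (0.0 <= artifact_fraction < 1.0):
            raise ValueError("artifact_fraction must lie in [0, 1)")
        vol = volume_um3 * (1.0 - artifact_fraction) / factors.s_vol
    return DensityEstimate(n_included=int(n), cf_volume_um3=vol,
                           density_per_um3=n / vol, corrected=corrected)
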