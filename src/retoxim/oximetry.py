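"""Stern-Volmer conversion of lifetimes to PO2 and vessel-ROI oximetry.

Molecular oxygen quenches the oxyphor's phosphorescence; the quenching
follows the Stern-Volmer relation

    1/tau = 1/tau0 + kq * PO2

so ``PO2 = (1/tau - 1/tau0) / kq``.  Tissue maps are averaged across
replicate acquisitions in the PO2 domain; vessel tensions are read out
as the mean over a circular ROI per replicate and then averaged over
replicates, mirroring the acquisition protocol (three repeats per
channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lifetime import LifetimeMap
from .physiology import OxyphorCalibration

__all__ = [
    "PO2Map",
    "CircleROI",
    "VesselMeasurement",
    "stern_volmer_po2",
    "stern_volmer_tau",
    "po2_map",
    "average_replicate_maps",
    "vessel_po2",
    "cohort_vessel_means",
]


@dataclass
class PO2Map:
    """Per-pixel oxygen tension map with validity mask."""

    po2_mmHg: np.ndarray
    valid: np.ndarray
    channel: str
    y_pixel_um: float = 3.0
    z_pixel_um: float = 4.5
    n_clipped: int = 0


@dataclass(frozen=True)
class CircleROI:
    """Circular vessel ROI in pixel coordinates (y vertical, z axial)."""

    center_y: float
    center_z: float
    radius_px: float
    label: str = "artery"

    def __post_init__(self) -> None:
        if self.label not in ("artery", "vein"):
            raise ValueError(f"label must be 'artery' or 'vein', got {self.label!r}")
        if not self.radius_px > 0:
            raise ValueError("radius_px must be positive")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, zz = np.ogrid[: shape[0], : shape[1]]
        return (yy - self.center_y) ** 2 + (zz - self.center_z) ** 2 <= self.radius_px**2


@dataclass
class VesselMeasurement:
    """PO2 readout of one vessel: per-replicate means and their average."""

    label: str
    roi: CircleROI
    per_replicate_po2: list = field(default_factory=list)
    mean_po2: float | None = None
    missing: bool = False


def stern_volmer_po2(tau_s, calib: OxyphorCalibration):
    """Convert lifetime(s) to PO2 in mmHg: ``(1/tau - 1/tau0) / kq``.

    Raises on non-positive lifetimes; NaNs propagate (used for invalid
    pixels).  Negative outputs are returned as-is — map-level clipping
    policy lives in :func:`po2_map`.
    """
    tau = np.asarray(tau_s, dtype=float)
    if np.any(tau[np.isfinite(tau)] <= 0):
        raise ValueError("lifetimes must be positive")
    po2 = (1.0 / tau - 1.0 / calib.tau0_s) / calib.kq
    if np.isscalar(tau_s):
        return float(po2)
    return po2


def stern_volmer_tau(po2_mmHg, calib: OxyphorCalibration):
    """Inverse map: lifetime produced by a given PO2 (the forward model)."""
    po2 = np.asarray(po2_mmHg, dtype=float)
    if np.any(po2[np.isfinite(po2)] < 0):
        raise ValueError("PO2 must be non-negative")
    tau = 1.0 / (1.0 / calib.tau0_s + calib.kq * po2)
    if np.isscalar(po2_mmHg):
        return float(tau)
    return tau


def po2_map(
    lt: LifetimeMap, calib: OxyphorCalibration, neg_eps_mmHg: float = 1.0
) -> PO2Map:
    """Element-wise Stern-Volmer conversion of a lifetime map.

    Slightly negative tensions (within ``neg_eps_mmHg`` of zero), which
    arise from noise at near-zero oxygen, are clipped to 0 and counted;
    tensions below ``-neg_eps_mmHg`` indicate a calibration mismatch and
    are invalidated instead.
    """
    po2 = np.full(lt.tau_s.shape, np.nan)
    valid = lt.valid.copy()
    v = valid & np.isfinite(lt.tau_s)
    po2[v] = (1.0 / lt.tau_s[v] - 1.0 / calib.tau0_s) / calib.kq

    too_neg = v & (po2 <= -neg_eps_mmHg)
    valid[too_neg] = False
    po2[too_neg] = np.nan
    clip = valid & np.isfinite(po2) & (po2 < 0)
    po2[clip] = 0.0

    return PO2Map(
        po2_mmHg=po2,
        valid=valid,
        channel=lt.channel,
        y_pixel_um=lt.y_pixel_um,
        z_pixel_um=lt.z_pixel_um,
        n_clipped=int(np.count_nonzero(clip)),
    )


def average_replicate_maps(maps: Sequence[PO2Map]) -> PO2Map:
    """Per-pixel mean over replicate PO2 maps.

    A pixel is valid in the mean only when valid in every replicate
    (mask conjunction), so replicate dropouts never bias the average.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to average")
    shape = maps[0].po2_mmHg.shape
    channel = maps[0].channel
    for m in maps[1:]:
        if m.po2_mmHg.shape != shape:
            raise ValueError("replicate maps have mismatched shapes")
        if m.channel != channel:
            raise ValueError("replicate maps have mismatched channels")
    valid = np.logical_and.reduce([m.valid for m in maps])
    stackd = np.stack([m.po2_mmHg for m in maps])
    mean = np.full(shape, np.nan)
    mean[valid] = np.mean(stackd[:, valid], axis=0)
    return PO2Map(
        po2_mmHg=mean,
        valid=valid,
        channel=channel,
        y_pixel_um=maps[0].y_pixel_um,
        z_pixel_um=maps[0].z_pixel_um,
        n_clipped=sum(m.n_clipped for m in maps),
    )


def vessel_po2(maps: Sequence[PO2Map], roi: CircleROI) -> VesselMeasurement:
    """Measure one vessel: ROI mean per replicate, then mean of replicates.

    A replicate with no valid ROI pixel contributes nothing; if *no*
    replicate has valid pixels the measurement is flagged ``missing``.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps supplied")
    shape = maps[0].po2_mmHg.shape
    m = roi.mask(shape)
    if not m.any():
        raise ValueError("ROI lies outside the image bounds")
    per_rep = []
    for pm in maps:
        sel = m & pm.valid
        if sel.any():
            per_rep.append(float(np.mean(pm.po2_mmHg[sel])))
    if not per_rep:
        return VesselMeasurement(label=roi.label, roi=roi, missing=True)
    return VesselMeasurement(
        label=roi.label,
        roi=roi,
        per_replicate_po2=per_rep,
        mean_po2=float(np.mean(per_rep)),
    )


def cohort_vessel_means(
    vessels: Sequence[VesselMeasurement],
) -> tuple[float | None, float | None]:
    """Mean arterial and venous PO2 (PO2A, PO2V) over measured vessels.

    Vessels flagged missing are skipped; an absent vessel type yields
    ``None`` for that entry.
    """
    po2a = [v.mean_po2 for v in vessels if v.label == "artery" and not v.missing]
    po2v = [v.mean_po2 for v in vessels if v.label == "vein" and not v.missing]
    return (
        float(np.mean(po2a)) if po2a else None,
        float(np.mean(po2v)) if po2v else None,
    )
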