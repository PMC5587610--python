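"""Forward model: ground-truth retinal PO2 scenes and synthetic stacks.

The optical-section geometry maps retinal depth onto one image axis: an
oblique excitation line makes the emission from deeper tissue appear
laterally displaced, so a single camera frame carries a vertical (y)
axis along the retina and an axial (z) axis across its depth.  A scene
holds a ground-truth tissue PO2 field over (y, fractional depth), a
curved chorioretinal interface trace, and a handful of vessels (circular
cross-sections in the inner retina) with known intravascular PO2.

``render_phase_stacks`` pushes the scene through the same physics the
analysis inverts: Stern-Volmer lifetimes, then the single-harmonic
homodyne intensity model

    I_k = A * (1 + m * M(tau) * cos(theta_k - phi(tau)))

per phase step, plus additive Gaussian camera noise.  The square-wave
chopper and gated-intensifier detection of the real instrument are
represented by this fundamental harmonic, consistent with the estimator.
Replicates differ only in their noise draws; one seed fixes everything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .diffusion import ThreeLayerParams, three_layer_po2
from .lifetime import PhaseStack
from .oximetry import stern_volmer_tau
from .physiology import (
    DEFAULT_CALIBRATIONS,
    OxyphorCalibration,
    default_dissociation_curve,
)

__all__ = [
    "VesselTruth",
    "AcquisitionSettings",
    "SceneTruth",
    "build_scene",
    "render_phase_stacks",
    "write_fixture",
    "read_fixture_stacks",
]


@dataclass(frozen=True)
class VesselTruth:
    """A vessel cross-section in the scene: circle in pixel coordinates."""

    label: str
    center_y: float
    radius: float
    po2: float

    def __post_init__(self) -> None:
        if self.label not in ("artery", "vein"):
            raise ValueError("vessel label must be 'artery' or 'vein'")
        if self.po2 < 0:
            raise ValueError("vessel po2 must be non-negative")
        if not self.radius > 0:
            raise ValueError("vessel radius must be positive")


@dataclass(frozen=True)
class AcquisitionSettings:
    """Phase-stepping acquisition parameters.

    Defaults follow the dual-oxyphor protocol: 10 phase steps covering
    0-180 deg (18 deg increments), 1.6 kHz modulation, 3 replicate
    acquisitions per channel.
    """

    n_phases: int = 10
    phases_deg: tuple = ()
    modulation_freq_hz: float = 1600.0
    modulation_depth: float = 0.8
    n_replicates: int = 3
    amplitude: float = 1000.0

    def __post_init__(self) -> None:
        if not self.phases_deg:
            step = 180.0 / self.n_phases
            object.__setattr__(
                self, "phases_deg", tuple(step * k for k in range(self.n_phases))
            )
        phases = np.asarray(self.phases_deg, dtype=float)
        if phases.size != self.n_phases:
            raise ValueError("phases_deg length must equal n_phases")
        if np.any(np.diff(phases) <= 0):
            raise ValueError("phase angles must be strictly increasing")
        if phases[0] < 0 or phases[-1] >= 180:
            raise ValueError("phase angles must lie in [0, 180) degrees")
        if not self.modulation_freq_hz > 0:
            raise ValueError("modulation_freq_hz must be positive")
        if not 0 < self.modulation_depth <= 1:
            raise ValueError("modulation_depth must be in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SceneTruth:
    """Ground-truth scene: geometry, tissue PO2 field and vessels."""

    height_px: int
    depth_px: int
    y_pixel_um: float
    z_pixel_um: float
    interface_trace: np.ndarray
    retina_thickness_um: float
    depth_grid: np.ndarray
    tissue_po2: np.ndarray  # (height_px, len(depth_grid)) over fractional depth
    vessels: list
    outer_params: ThreeLayerParams
    inner_po2_base: float
    noise_sigma: float
    seed: int
    curvature_px_per_px2: float = 0.0

    @property
    def thickness_px(self) -> float:
        return self.retina_thickness_um / self.z_pixel_um

    @property
    def inner_trace(self) -> np.ndarray:
        """Per-row axial position of the inner (vitreal) retinal surface."""
        return self.interface_trace - self.thickness_px

    def vessel_center_z(self, vessel: VesselTruth) -> float:
        """Axial center of a vessel: quarter-depth (inner retina) at its row."""
        row = int(round(vessel.center_y))
        row = min(max(row, 0), self.height_px - 1)
        return float(self.inner_trace[row] + 0.25 * self.thickness_px)

    def sample_tissue_po2(self, rows: np.ndarray, frac_depth: np.ndarray) -> np.ndarray:
        """Interpolate the tissue field at (row, fractional depth) pairs."""
        out = np.empty(rows.shape, dtype=float)
        for r in np.unique(rows):
            sel = rows == r
            out[sel] = np.interp(frac_depth[sel], self.depth_grid, self.tissue_po2[r])
        return out


_DEFAULT_VESSELS = (
    VesselTruth("artery", center_y=80.0, radius=8.0, po2=41.0),
    VesselTruth("vein", center_y=170.0, radius=8.0, po2=25.0),
    VesselTruth("artery", center_y=260.0, radius=8.0, po2=41.0),
)


def build_scene(
    height_px: int = 350,
    depth_px: int = 120,
    y_pixel_um: float = 3.0,
    z_pixel_um: float = 4.5,
    retina_thickness_um: float = 230.0,
    interface_z_px: float = 95.0,
    curvature_px_per_px2: float = 2.6e-4,
    outer_params: ThreeLayerParams | None = None,
    inner_po2_base: float = 23.0,
    artery_elevation_mmHg: float = 4.0,
    artery_elevation_sigma_px: float = 15.0,
    vessels: tuple = _DEFAULT_VESSELS,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_depth_samples: int = 201,
) -> SceneTruth:
    """Assemble a ground-truth scene.

    The outer half of every depth profile (50-100% fractional depth) is
    the three-layer diffusion solution for ``outer_params``; the inner
    half is a smooth field at ``inner_po2_base`` with a Gaussian
    elevation near each artery (tissue PO2 runs higher next to arteries)
    that tapers to zero at 50% depth so the field stays continuous.  The
    chorioretinal interface follows a quadratic in the row index with
    curvature ``curvature_px_per_px2`` (0 gives a flat interface).

    Default vessel tensions (arteries 41 mmHg, vein 25 mmHg) and inner
    tissue tension (23 mmHg) reproduce the healthy-rat operating point
    used throughout the tests.
    """
    if height_px <= 0 or depth_px <= 0:
        raise ValueError("image dimensions must be positive")
    if y_pixel_um <= 0 or z_pixel_um <= 0:
        raise ValueError("pixel sizes must be positive")
    if retina_thickness_um <= 0:
        raise ValueError("retina thickness must be positive")
    if inner_po2_base < 0:
        raise ValueError("inner_po2_base must be non-negative")

    if outer_params is None:
        # QO2 = 0.57 mL O2/100g/min spread over layer 2 = 20% of the outer
        # retina: q2 = 0.57 / (100 * 0.2).
        outer_params = ThreeLayerParams(
            pc_mmHg=60.0,
            pl_mmHg=inner_po2_base,
            x1_frac=0.2,
            x2_frac=0.4,
            q2=0.0285,
            L_um=retina_thickness_um / 2.0,
            Dk=1.97e-10 * 60.0,
        )

    rows = np.arange(height_px, dtype=float)
    center = (height_px - 1) / 2.0
    interface_trace = interface_z_px - curvature_px_per_px2 * (rows - center) ** 2
    if np.any(interface_trace < 0) or np.any(interface_trace >= depth_px):
        raise ValueError("interface trace leaves the axial field of view")
    thickness_px = retina_thickness_um / z_pixel_um
    if np.any(interface_trace - thickness_px < 0):
        raise ValueError("retina does not fit in the axial field of view")

    d = np.linspace(0.0, 1.0, n_depth_samples)
    outer = d >= 0.5
    profile = np.empty_like(d)
    profile[~outer] = inner_po2_base
    # fractional position from the chorioretinal interface: x = (1 - d) / 0.5
    profile[outer] = three_layer_po2((1.0 - d[outer]) * 2.0, outer_params)

    field2d = np.tile(profile, (height_px, 1))
    taper = np.clip(1.0 - 2.0 * d, 0.0, None)  # 1 at the vitreal surface, 0 at 50%
    for v in vessels:
        if v.label != "artery" or artery_elevation_mmHg == 0:
            continue
        bump = artery_elevation_mmHg * np.exp(
            -((rows - v.center_y) ** 2) / (2.0 * artery_elevation_sigma_px**2)
        )
        field2d += bump[:, None] * taper[None, :]
    if np.any(field2d < 0):
        raise ValueError("tissue PO2 field went negative; check parameters")

    return SceneTruth(
        height_px=height_px,
        depth_px=depth_px,
        y_pixel_um=y_pixel_um,
        z_pixel_um=z_pixel_um,
        interface_trace=interface_trace,
        retina_thickness_um=retina_thickness_um,
        depth_grid=d,
        tissue_po2=field2d,
        vessels=list(vessels),
        outer_params=outer_params,
        inner_po2_base=inner_po2_base,
        noise_sigma=noise_sigma,
        seed=seed,
        curvature_px_per_px2=curvature_px_per_px2,
    )


def _scene_po2_images(scene: SceneTruth) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the scene into per-pixel PO2 images (NaN where no dye).

    Returns (tissue_po2_img, vascular_po2_img), each (H, Z).
    """
    H, Z = scene.height_px, scene.depth_px
    zz = np.arange(Z, dtype=float)[None, :]
    iface = scene.interface_trace[:, None]
    inner = scene.inner_trace[:, None]
    in_band = (zz >= inner) & (zz <= iface)

    tissue = np.full((H, Z), np.nan)
    ry, rz = np.nonzero(in_band)
    frac = (rz - scene.inner_trace[ry]) / scene.thickness_px
    tissue[ry, rz] = scene.sample_tissue_po2(ry, np.clip(frac, 0.0, 1.0))

    vascular = np.full((H, Z), np.nan)
    yy = np.arange(H, dtype=float)[:, None]
    for v in scene.vessels:
        cz = scene.vessel_center_z(v)
        mask = (yy - v.center_y) ** 2 + (zz - cz) ** 2 <= v.radius**2
        vascular[mask] = v.po2
    return tissue, vascular


def _render_channel(
    po2_img: np.ndarray,
    scene: SceneTruth,
    acq: AcquisitionSettings,
    calib: OxyphorCalibration,
    channel: str,
    rng: np.random.Generator,
) -> list[PhaseStack]:
    H, Z = po2_img.shape
    present = np.isfinite(po2_img)
    tau = np.zeros((H, Z))
    tau[present] = stern_volmer_tau(po2_img[present], calib)

    omega = 2.0 * np.pi * acq.modulation_freq_hz
    wt = omega * tau
    phi = np.arctan(wt)
    M = 1.0 / np.sqrt(1.0 + wt**2)
    A = np.where(present, acq.amplitude, 0.0)

    theta = np.deg2rad(np.asarray(acq.phases_deg))
    clean = A[None] * (
        1.0 + acq.modulation_depth * M[None] * np.cos(theta[:, None, None] - phi[None])
    )
    clean[:, ~present] = 0.0

    stacks = []
    for rep in range(acq.n_replicates):
        noisy = clean
        if scene.noise_sigma > 0:
            noisy = clean + rng.normal(0.0, scene.noise_sigma, size=clean.shape)
        stacks.append(
            PhaseStack(
                images=noisy.copy(),
                phases_deg=np.asarray(acq.phases_deg),
                modulation_freq_hz=acq.modulation_freq_hz,
                y_pixel_um=scene.y_pixel_um,
                z_pixel_um=scene.z_pixel_um,
                channel=channel,
                replicate=rep,
            )
        )
    return stacks


def render_phase_stacks(
    scene: SceneTruth,
    acq: AcquisitionSettings | None = None,
    calib_tissue: OxyphorCalibration | None = None,
    calib_vascular: OxyphorCalibration | None = None,
) -> tuple[list[PhaseStack], list[PhaseStack]]:
    """Render noisy phase-delayed stacks for both oxyphor channels.

    Returns ``(tissue_stacks, vascular_stacks)``, ``n_replicates`` each.
    The tissue (G2) channel emits from the whole retinal band, the
    vascular (R0) channel only from within vessel cross-sections.  All
    randomness derives from ``scene.seed``.
    """
    acq = acq or AcquisitionSettings()
    calib_tissue = calib_tissue or DEFAULT_CALIBRATIONS["G2"]
    calib_vascular = calib_vascular or DEFAULT_CALIBRATIONS["R0"]
    tissue_po2, vascular_po2 = _scene_po2_images(scene)
    rng = np.random.default_rng(scene.seed)
    tissue = _render_channel(tissue_po2, scene, acq, calib_tissue, "tissue", rng)
    vascular = _render_channel(vascular_po2, scene, acq, calib_vascular, "vascular", rng)
    return tissue, vascular


def _ground_truth_dict(scene: SceneTruth) -> dict:
    """Reference values a fixture consumer can assert against."""
    inner = scene.depth_grid < 0.5
    outer = ~inner
    arteries = [v.po2 for v in scene.vessels if v.label == "artery"]
    veins = [v.po2 for v in scene.vessels if v.label == "vein"]
    from .oef import oef as _oef  # local import to avoid a cycle at import time

    po2a = float(np.mean(arteries)) if arteries else None
    po2v = float(np.mean(veins)) if veins else None
    oef_val = None
    if po2a and po2v is not None:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oef_val = _oef(po2a, po2v, default_dissociation_curve()).oef
    return {
        "po2a_mmHg": po2a,
        "po2v_mmHg": po2v,
        "vessels": [
            {
                "label": v.label,
                "center_y": v.center_y,
                "center_z": scene.vessel_center_z(v),
                "radius_px": v.radius,
                "po2_mmHg": v.po2,
            }
            for v in scene.vessels
        ],
        "mean_inner_tpo2_mmHg": float(np.mean(scene.tissue_po2[:, inner])),
        "max_outer_tpo2_mmHg": float(np.max(scene.tissue_po2[:, outer])),
        "min_outer_tpo2_mmHg": float(np.min(scene.tissue_po2[:, outer])),
        "qo2_mLO2_per_100g_min": scene.outer_params.qo2,
        "oef": oef_val,
        "outer_params": {
            "pc_mmHg": scene.outer_params.pc_mmHg,
            "pl_mmHg": scene.outer_params.pl_mmHg,
            "x1_frac": scene.outer_params.x1_frac,
            "x2_frac": scene.outer_params.x2_frac,
            "q2": scene.outer_params.q2,
            "L_um": scene.outer_params.L_um,
            "Dk": scene.outer_params.Dk,
        },
        "retina_thickness_um": scene.retina_thickness_um,
        "inner_po2_base_mmHg": scene.inner_po2_base,
        "interface_z_px": float(np.max(scene.interface_trace)),
        "curvature_px_per_px2": scene.curvature_px_per_px2,
        "noise_sigma": scene.noise_sigma,
        "seed": scene.seed,
    }


def write_fixture(
    scene: SceneTruth,
    tissue_stacks: list[PhaseStack],
    vascular_stacks: list[PhaseStack],
    directory: str | Path,
    acq: AcquisitionSettings | None = None,
) -> list[Path]:
    """Write a fixture set: TIFFs, YAML sidecars, ROIs and ground truth.

    One multi-page float32 TIFF per channel per replicate (K pages each),
    a YAML metadata sidecar next to every TIFF, ``rois.json`` with the
    vessel ROIs and ``ground_truth.json`` with the scene's reference
    values.  Returns the list of paths written.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc

    written: list[Path] = []
    for stacks in (tissue_stacks, vascular_stacks):
        for st in stacks:
            stem = f"{st.channel}_rep{st.replicate}"
            tif = directory / f"{stem}.tif"
            try:
                tifffile.imwrite(tif, st.images.astype(np.float32))
            except OSError as exc:
                raise OSError(f"failed writing {tif}: {exc}") from exc
            meta = {
                "channel": st.channel,
                "replicate": int(st.replicate),
                "phases_deg": [float(p) for p in st.phases_deg],
                "modulation_freq_hz": float(st.modulation_freq_hz),
                "modulation_depth": float(acq.modulation_depth) if acq else None,
                "y_pixel_um": float(st.y_pixel_um),
                "z_pixel_um": float(st.z_pixel_um),
            }
            yml = directory / f"{stem}.yaml"
            yml.write_text(yaml.safe_dump(meta, sort_keys=True))
            written += [tif, yml]

    rois = directory / "rois.json"
    rois.write_text(
        json.dumps(
            [
                {
                    "label": v.label,
                    "center_y": v.center_y,
                    "center_z": scene.vessel_center_z(v),
                    "radius_px": v.radius,
                }
                for v in scene.vessels
            ],
            indent=2,
            sort_keys=True,
        )
    )
    truth = directory / "ground_truth.json"
    truth.write_text(json.dumps(_ground_truth_dict(scene), indent=2, sort_keys=True))
    written += [rois, truth]
    return written


def read_fixture_stacks(directory: str | Path) -> list[PhaseStack]:
    """Load every TIFF + YAML sidecar pair in a fixture directory."""
    directory = Path(directory)
    stacks = []
    for yml in sorted(directory.glob("*.yaml")):
        tif = yml.with_suffix(".tif")
        if not tif.exists():
            continue
        meta = yaml.safe_load(yml.read_text())
        stacks.append(
            PhaseStack(
                images=tifffile.imread(tif),
                phases_deg=np.asarray(meta["phases_deg"], dtype=float),
                modulation_freq_hz=float(meta["modulation_freq_hz"]),
                y_pixel_um=float(meta["y_pixel_um"]),
                z_pixel_um=float(meta["z_pixel_um"]),
                channel=meta["channel"],
                replicate=int(meta["replicate"]),
            )
        )
    return stacks
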