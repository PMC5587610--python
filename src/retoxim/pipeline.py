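"""End-to-end orchestration: stacks in, oxygenation metrics out.

The full analysis runs two parallel branches off the phase-delayed
stacks of one imaging session:

vascular (R0): lifetime -> Stern-Volmer PO2 -> vessel-ROI tensions ->
    PO2A / PO2V -> inner retinal OEF;
tissue (G2): lifetime -> PO2 per replicate -> replicate mean ->
    curvature flattening -> 6 x 4 px anisotropic smoothing -> 10-px
    depth profiles -> profile metrics -> per-profile three-layer fit ->
    mean outer retinal QO2.

Every threshold, constant, exclusion and the seed are echoed to a
structured plain-text log so a run can be audited; outputs are byte
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import diffusion, oximetry, profiles as prof_mod
from .oef import oef as _compute_oef
from .lifetime import PhaseStack, estimate_lifetime_map
from .physiology import (
    DissociationCurve,
    OxyphorCalibration,
    default_calibration,
    default_dissociation_curve,
    default_dk_per_min,
)
from .scene import read_fixture_stacks

__all__ = ["RunConfig", "PipelineError", "validate_stack_set", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: str | Path
    output_dir: str | Path
    rois_path: str | Path | None = None
    calibrations: dict = field(default_factory=dict)  # channel -> OxyphorCalibration
    dissociation: DissociationCurve | None = None
    dk_per_min: float | None = None
    amplitude_threshold: float = 0.10
    neg_eps_mmHg: float = 1.0
    filter_size_y: int = 6
    filter_size_z: int = 4
    bin_px: int = 10
    detect_smooth_px: int = 5
    inner_threshold: float = 0.10
    expected_n_phases: int = 10
    use_default_calibrations: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        calibs = {}
        for ch, c in (raw.pop("calibrations", None) or {}).items():
            calibs[ch] = OxyphorCalibration(
                name=c.get("name", ch),
                tau0_s=float(c["tau0_s"]),
                kq=float(c["kq"]),
                source=c.get("source", str(path)),
            )
        curve = None
        if "dissociation" in raw:
            d = raw.pop("dissociation")
            curve = DissociationCurve(
                p50_mmHg=float(d["p50_mmHg"]),
                hill_n=float(d["hill_n"]),
                hb_capacity=float(d["hb_capacity"]),
                solubility=float(d.get("solubility", 0.0)),
                source=d.get("source", str(path)),
            )
        return cls(calibrations=calibs, dissociation=curve, **raw)


def validate_stack_set(
    directory: str | Path, expected_n_phases: int | None = None
) -> list[str]:
    """Check a stack directory for protocol violations; returns messages.

    Verifies page counts against the sidecar phase list (and optionally
    an expected count), shape consistency across stacks, phase angles in
    [0, 180), and that both channels are present.  An empty list means
    the set is usable.
    """
    directory = Path(directory)
    violations: list[str] = []
    shapes = {}
    channels = set()
    found = False
    for yml in sorted(directory.glob("*.yaml")):
        tif = yml.with_suffix(".tif")
        if not tif.exists():
            violations.append(f"{yml.name}: sidecar without a TIFF stack")
            continue
        found = True
        meta = yaml.safe_load(yml.read_text())
        arr = tifffile.imread(tif)
        if arr.ndim == 2:
            arr = arr[None]
        phases = meta.get("phases_deg", [])
        channels.add(meta.get("channel"))
        if len(phases) != arr.shape[0]:
            violations.append(
                f"{tif.name}: {arr.shape[0]} pages but {len(phases)} phase angles"
            )
        if expected_n_phases is not None and arr.shape[0] != expected_n_phases:
            violations.append(
                f"{tif.name}: {arr.shape[0]} pages, expected {expected_n_phases}"
            )
        if phases and (min(phases) < 0 or max(phases) >= 180):
            violations.append(f"{tif.name}: phase angles outside [0, 180) deg")
        shapes.setdefault(arr.shape[1:], []).append(tif.name)
    if not found:
        violations.append(f"{directory}: no TIFF/YAML stack pairs found")
    if len(shapes) > 1:
        violations.append(
            "inconsistent image shapes: "
            + "; ".join(f"{s}: {', '.join(names)}" for s, names in sorted(shapes.items(), key=str))
        )
    for ch in ("tissue", "vascular"):
        if found and ch not in channels:
            violations.append(f"missing channel: {ch}")
    return violations


def _load_rois(path: Path) -> list[oximetry.CircleROI]:
    raw = json.loads(path.read_text())
    return [
        oximetry.CircleROI(
            center_y=float(r["center_y"]),
            center_z=float(r["center_z"]),
            radius_px=float(r["radius_px"]),
            label=r["label"],
        )
        for r in raw
    ]


def _write_map_tiff(path: Path, pmap) -> None:
    img = np.where(pmap.valid, pmap.po2_mmHg, np.nan).astype(np.float32)
    tifffile.imwrite(path, img)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle as a dict.

    Writes PO2 map TIFFs, profiles/metrics CSVs, fit JSON, a summary
    JSON and a structured log into ``cfg.output_dir``.  Any stage
    failure removes this run's partial outputs and raises
    :class:`PipelineError` naming the stage.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log: list[str] = []

    def emit(line: str) -> None:
        log.append(line)

    def fail(stage: str, message: str) -> PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        return PipelineError(stage, message)

    # --- configuration / constants ---------------------------------
    calibs = dict(cfg.calibrations)
    if cfg.use_default_calibrations:
        for ch, oxyphor in (("tissue", "G2"), ("vascular", "R0")):
            if ch not in calibs:
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    calibs[ch] = default_calibration(oxyphor)
                for w in wlist:
                    emit(f"warning: {w.message}")
    curve = cfg.dissociation
    dk = cfg.dk_per_min
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        if curve is None:
            curve = default_dissociation_curve()
        if dk is None:
            dk = default_dk_per_min()
    for w in wlist:
        emit(f"warning: {w.message}")

    emit(f"seed: {cfg.seed}")
    for ch, c in sorted(calibs.items()):
        emit(f"calibration[{ch}]: {c.name} tau0_s={c.tau0_s:.9g} kq={c.kq:.9g}")
    emit(
        "dissociation: p50=%.9g n=%.9g capacity=%.9g solubility=%.9g"
        % (curve.p50_mmHg, curve.hill_n, curve.hb_capacity, curve.solubility)
    )
    emit(f"Dk_per_min: {dk:.9g}")
    emit(
        f"thresholds: amplitude={cfg.amplitude_threshold} neg_eps={cfg.neg_eps_mmHg} "
        f"inner={cfg.inner_threshold} detect_smooth_px={cfg.detect_smooth_px}"
    )
    emit(f"filter: {cfg.filter_size_y}x{cfg.filter_size_z} px, bin: {cfg.bin_px} px")

    # --- load and validate ------------------------------------------
    try:
        violations = validate_stack_set(cfg.input_dir, cfg.expected_n_phases)
        for v in violations:
            emit(f"validation: {v}")
        stacks = read_fixture_stacks(cfg.input_dir)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise fail("load", str(exc)) from exc
    by_channel: dict[str, list[PhaseStack]] = {"tissue": [], "vascular": []}
    for st in stacks:
        by_channel.setdefault(st.channel, []).append(st)
    for ch in ("tissue", "vascular"):
        if not by_channel[ch]:
            raise fail("load", f"no stacks for channel {ch!r} in {cfg.input_dir}")
        emit(f"stacks[{ch}]: {len(by_channel[ch])} replicates")
    for ch in by_channel:
        if by_channel[ch] and ch not in calibs:
            raise fail("load", f"missing calibration for channel {ch!r}")

    # --- lifetime and PO2 -------------------------------------------
    po2_maps: dict[str, list[oximetry.PO2Map]] = {}
    try:
        for ch, sts in by_channel.items():
            maps = []
            for st in sorted(sts, key=lambda s: s.replicate):
                lt = estimate_lifetime_map(st, cfg.amplitude_threshold)
                pm = oximetry.po2_map(lt, calibs[ch], cfg.neg_eps_mmHg)
                if pm.n_clipped:
                    emit(f"po2[{ch} rep{st.replicate}]: clipped {pm.n_clipped} px to 0")
                maps.append(pm)
            po2_maps[ch] = maps
    except Exception as exc:  # noqa: BLE001
        raise fail("lifetime", str(exc)) from exc

    # --- vascular branch --------------------------------------------
    try:
        rois_path = Path(cfg.rois_path or Path(cfg.input_dir) / "rois.json")
        if not rois_path.exists():
            raise FileNotFoundError(f"ROI definitions not found: {rois_path}")
        rois = _load_rois(rois_path)
        vessels = [oximetry.vessel_po2(po2_maps["vascular"], roi) for roi in rois]
        for v in vessels:
            if v.missing:
                emit(f"vessel {v.label} @y={v.roi.center_y}: no valid pixels, skipped")
        po2a, po2v = oximetry.cohort_vessel_means(vessels)
        oef_res = None
        if po2a is not None and po2v is not None:
            oef_res = _compute_oef(po2a, po2v, curve)
        else:
            emit("oef: skipped (missing arterial or venous measurement)")
    except Exception as exc:  # noqa: BLE001
        raise fail("vascular", str(exc)) from exc

    # --- tissue branch ----------------------------------------------
    try:
        tissue_mean = oximetry.average_replicate_maps(po2_maps["tissue"])
        flat = prof_mod.flatten_curvature(
            tissue_mean, cfg.detect_smooth_px, cfg.inner_threshold
        )
        emit(f"flatten: {int(flat.row_valid.sum())}/{flat.row_valid.size} rows usable")
        smoothed, sm_ok = prof_mod.smooth_anisotropic(
            flat.po2_mmHg, flat.valid, cfg.filter_size_y, cfg.filter_size_z
        )
        flat.po2_mmHg = smoothed
        flat.valid = flat.valid & sm_ok
        profs = prof_mod.extract_profiles(flat, cfg.bin_px)
        emit(f"profiles: {sum(p.usable for p in profs)}/{len(profs)} usable")
    except Exception as exc:  # noqa: BLE001
        raise fail("tissue", str(exc)) from exc

    # --- per-profile metrics and QO2 fits ---------------------------
    try:
        metrics_rows = []
        fit_records = []
        fits = []
        for i, p in enumerate(profs):
            m = prof_mod.profile_metrics(p)
            row = {
                "profile": i,
                "y_center_um": p.y_center_um,
                "thickness_um": p.thickness_um,
                "usable": p.usable,
                "max_outer_tpo2": m.max_outer_tpo2,
                "min_outer_tpo2": m.min_outer_tpo2,
                "mean_inner_tpo2": m.mean_inner_tpo2,
                "qo2": np.nan,
                "fit_r2": np.nan,
                "fit_usable": False,
            }
            if p.usable:
                outer = p.fractional_depth >= 0.5
                x_frac = (1.0 - p.fractional_depth[outer]) * 2.0
                # The anisotropic filter's axial arm smooths the narrow
                # consuming layer, so fit the box-averaged model; samples
                # whose window crosses the chorioretinal band edge carry an
                # unmodeled truncated window and are left out of the fit.
                outer_px = (p.thickness_um / 2.0) / flat.z_pixel_um
                window_x = cfg.filter_size_z / outer_px
                keep = x_frac >= window_x / 2.0
                x_frac, y_fit = x_frac[keep], p.tpo2_mmHg[outer][keep]
                if x_frac.size >= 8:
                    fit = diffusion.fit_three_layer(
                        x_frac,
                        y_fit,
                        L_um=p.thickness_um / 2.0,
                        Dk=dk,
                        seed=cfg.seed + i,
                        window_x=window_x,
                    )
                    fits.append(fit)
                    if not fit.usable:
                        emit(
                            f"fit[profile {i}]: excluded "
                            f"(converged={fit.converged}, at_bound="
                            f"{[k for k, v in fit.at_bound.items() if v]})"
                        )
                    row.update(
                        qo2=fit.qo2_mLO2_per_100g_min,
                        fit_r2=fit.r2,
                        fit_usable=fit.usable,
                    )
                    fit_records.append(
                        {
                            "profile": i,
                            "pc_mmHg": fit.params.pc_mmHg,
                            "pl_mmHg": fit.params.pl_mmHg,
                            "x1_frac": fit.params.x1_frac,
                            "x2_frac": fit.params.x2_frac,
                            "q2": fit.params.q2,
                            "L_um": fit.params.L_um,
                            "qo2_mLO2_per_100g_min": fit.qo2_mLO2_per_100g_min,
                            "rss": fit.rss,
                            "r2": fit.r2,
                            "converged": fit.converged,
                            "at_bound": fit.at_bound,
                        }
                    )
            metrics_rows.append(row)
        qo2_mean, n_excl = diffusion.mean_qo2(fits)
        emit(f"qo2: {len(fits)} fits, {n_excl} excluded from mean")
    except Exception as exc:  # noqa: BLE001
        raise fail("qo2", str(exc)) from exc

    # --- outputs -----------------------------------------------------
    try:
        vasc_mean = oximetry.average_replicate_maps(po2_maps["vascular"])
        p = out_dir / "po2_vascular.tif"
        _write_map_tiff(p, vasc_mean)
        written.append(p)
        p = out_dir / "po2_tissue.tif"
        _write_map_tiff(p, tissue_mean)
        written.append(p)
        p = out_dir / "po2_tissue_flat.tif"
        _write_map_tiff(p, flat)
        written.append(p)

        prof_frames = []
        for i, pr in enumerate(profs):
            if not pr.usable:
                continue
            prof_frames.append(
                pd.DataFrame(
                    {
                        "profile": i,
                        "y_center_um": pr.y_center_um,
                        "fractional_depth": pr.fractional_depth,
                        "tpo2_mmHg": pr.tpo2_mmHg,
                        "thickness_um": pr.thickness_um,
                    }
                )
            )
        profiles_csv = out_dir / "profiles.csv"
        if prof_frames:
            pd.concat(prof_frames, ignore_index=True).to_csv(profiles_csv, index=False)
        else:
            profiles_csv.write_text(
                "profile,y_center_um,fractional_depth,tpo2_mmHg,thickness_um\n"
            )
        written.append(profiles_csv)

        metrics_csv = out_dir / "metrics.csv"
        pd.DataFrame(metrics_rows).to_csv(metrics_csv, index=False)
        written.append(metrics_csv)

        fits_json = out_dir / "fits.json"
        fits_json.write_text(json.dumps(fit_records, indent=2, sort_keys=True))
        written.append(fits_json)

        vessels_csv = out_dir / "vessels.csv"
        pd.DataFrame(
            [
                {
                    "label": v.label,
                    "center_y": v.roi.center_y,
                    "center_z": v.roi.center_z,
                    "radius_px": v.roi.radius_px,
                    "mean_po2_mmHg": v.mean_po2,
                    "n_replicates": len(v.per_replicate_po2),
                    "missing": v.missing,
                }
                for v in vessels
            ]
        ).to_csv(vessels_csv, index=False)
        written.append(vessels_csv)

        mdf = pd.DataFrame(metrics_rows)
        usable = mdf[mdf["usable"]]
        summary = {
            "po2a_mmHg": po2a,
            "po2v_mmHg": po2v,
            "oef": oef_res.oef if oef_res else None,
            "sa": oef_res.sa if oef_res else None,
            "sv": oef_res.sv if oef_res else None,
            "ca_mLO2_per_mL": oef_res.ca if oef_res else None,
            "cv_mLO2_per_mL": oef_res.cv if oef_res else None,
            "mean_inner_tpo2_mmHg": float(usable["mean_inner_tpo2"].mean()),
            "max_outer_tpo2_mmHg": float(usable["max_outer_tpo2"].mean()),
            "min_outer_tpo2_mmHg": float(usable["min_outer_tpo2"].mean()),
            "mean_qo2_mLO2_per_100g_min": qo2_mean,
            "n_profiles": int(len(usable)),
            "n_fits": len(fits),
            "n_fits_excluded": n_excl,
            "seed": cfg.seed,
        }
        summary_json = out_dir / "summary.json"
        summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True))
        written.append(summary_json)

        log_path = out_dir / "run.log"
        log_path.write_text("\n".join(log) + "\n")
        written.append(log_path)
    except Exception as exc:  # noqa: BLE001
        raise fail("write", str(exc)) from exc

    summary["violations"] = violations
    summary["outputs"] = [str(p) for p in written]
    return summary
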