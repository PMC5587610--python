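"""Physiological and photophysical constants used across the pipeline.

The oxyphor calibration constants (zero-oxygen lifetime ``tau0`` and
quenching constant ``kq``), the rat oxyhemoglobin dissociation curve and
the retinal oxygen diffusion-solubility product ``Dk`` are *required*
configuration: the shipped defaults are literature placeholders and every
accessor that falls back to them emits a :class:`CalibrationDefaultWarning`
so a run can always be audited for un-reviewed constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "OxyphorCalibration",
    "DissociationCurve",
    "CalibrationDefaultWarning",
    "default_calibration",
    "default_dissociation_curve",
    "default_dk_per_min",
    "DEFAULT_CALIBRATIONS",
    "DEFAULT_DISSOCIATION_CURVE",
    "DEFAULT_DK_ML_O2_PER_CM_S_MMHG",
]


class CalibrationDefaultWarning(UserWarning):
    """Emitted whenever a literature-placeholder constant is used."""


@dataclass(frozen=True)
class OxyphorCalibration:
    """Stern-Volmer calibration of one phosphorescent oxygen probe.

    Parameters
    ----------
    name
        Probe identifier; ``"R0"`` (intravascular) or ``"G2"`` (intravitreal,
        tissue) in the standard dual-probe protocol.
    tau0_s
        Phosphorescence lifetime in a zero-oxygen environment, seconds.
    kq
        Oxygen quenching constant, mmHg^-1 s^-1.
    source
        Citation or provenance string for the constants.
    """

    name: str
    tau0_s: float
    kq: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.tau0_s > 0:
            raise ValueError(f"tau0_s must be positive, got {self.tau0_s}")
        if not self.kq > 0:
            raise ValueError(f"kq must be positive, got {self.kq}")


@dataclass(frozen=True)
class DissociationCurve:
    """Hill-form oxyhemoglobin dissociation curve plus blood O2 capacity.

    ``p50_mmHg`` is the half-saturation oxygen tension, ``hill_n`` the
    cooperativity exponent, ``hb_capacity`` the oxygen carried by fully
    saturated hemoglobin (mL O2 per mL blood) and ``solubility`` the
    dissolved-oxygen coefficient (mL O2 mL^-1 mmHg^-1; set to 0 to drop
    the dissolved term).
    """

    p50_mmHg: float
    hill_n: float
    hb_capacity: float
    solubility: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.p50_mmHg > 0:
            raise ValueError("p50_mmHg must be positive")
        if not self.hill_n > 0:
            raise ValueError("hill_n must be positive")
        if not self.hb_capacity > 0:
            raise ValueError("hb_capacity must be positive")
        if self.solubility < 0:
            raise ValueError("solubility must be non-negative")


#: Literature placeholder calibrations for the two oxyphors.  The study
#: protocol uses Pd-porphyrin probes whose constants are instrument- and
#: environment-dependent; review before quantitative use.
DEFAULT_CALIBRATIONS = {
    "R0": OxyphorCalibration(
        name="R0",
        tau0_s=637e-6,
        kq=381.0,
        source="literature placeholder (Pd-meso-tetra(4-carboxyphenyl)porphine)",
    ),
    "G2": OxyphorCalibration(
        name="G2",
        tau0_s=251e-6,
        kq=281.0,
        source="literature placeholder (Oxyphor G2)",
    ),
}

#: Literature placeholder rat oxyhemoglobin dissociation curve.
DEFAULT_DISSOCIATION_CURVE = DissociationCurve(
    p50_mmHg=36.0,
    hill_n=2.7,
    hb_capacity=0.2,
    solubility=3e-5,
    source="literature placeholder (rat hemoglobin, Hill form)",
)

#: Retinal oxygen diffusion coefficient x solubility product,
#: mL O2 cm^-1 s^-1 mmHg^-1 (literature placeholder).
DEFAULT_DK_ML_O2_PER_CM_S_MMHG = 1.97e-10


def default_calibration(name: str) -> OxyphorCalibration:
    """Return the placeholder calibration for oxyphor ``name`` (with warning)."""
    try:
        calib = DEFAULT_CALIBRATIONS[name]
    except KeyError:
        raise KeyError(
            f"no default calibration for oxyphor {name!r}; known: "
            f"{sorted(DEFAULT_CALIBRATIONS)}"
        ) from None
    warnings.warn(
        f"using literature placeholder calibration for oxyphor {name!r} "
        f"(tau0={calib.tau0_s:g} s, kq={calib.kq:g} /mmHg/s); supply "
        "measured constants for quantitative work",
        CalibrationDefaultWarning,
        stacklevel=2,
    )
    return calib


def default_dissociation_curve() -> DissociationCurve:
    """Return the placeholder rat dissociation curve (with warning)."""
    warnings.warn(
        "using literature placeholder rat oxyhemoglobin dissociation curve "
        "(p50=36 mmHg, n=2.7, capacity=0.2, solubility=3e-5)",
        CalibrationDefaultWarning,
        stacklevel=2,
    )
    return DEFAULT_DISSOCIATION_CURVE


def default_dk_per_min() -> float:
    """Placeholder Dk converted to mL O2 cm^-1 min^-1 mmHg^-1 (with warning)."""
    warnings.warn(
        "using literature placeholder retinal Dk = 1.97e-10 mL O2/cm/s/mmHg",
        CalibrationDefaultWarning,
        stacklevel=2,
    )
    return DEFAULT_DK_ML_O2_PER_CM_S_MMHG * 60.0
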