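"""Per-pixel phosphorescence lifetime from phase-delayed image stacks.

In frequency-domain (homodyne) lifetime imaging both the excitation and
the detector gain are modulated at a common frequency f and the relative
phase between them is stepped.  The detected intensity at phase step
theta_k follows

    I_k = A * (1 + m * M(tau) * cos(theta_k - phi(tau)))

with phase lag ``phi = arctan(omega tau)``, demodulation
``M = (1 + (omega tau)^2)^(-1/2)`` and ``omega = 2 pi f``.  Expanding the
cosine makes this linear in (a, b, c) = (A, B cos phi, B sin phi), so the
lifetime follows from an exact linear least-squares fit of

    I_k = a + b cos(theta_k) + c sin(theta_k)

via ``phi = atan2(c, b)`` and ``tau = tan(phi) / omega``.  With phase
steps covering only half a period (0-180 deg) the cosine/sine basis is
not orthogonal, so the normal equations are solved exactly instead of
using Fourier quadrature (which would be biased here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "PhaseStack",
    "LifetimeMap",
    "PhaseFit",
    "LifetimeFitError",
    "fit_phase_pixel",
    "estimate_lifetime_map",
    "modulation_lifetime",
]


class LifetimeFitError(ValueError):
    """Raised when the phase design is unusable (too few / degenerate phases)."""


@dataclass
class PhaseStack:
    """One channel/replicate acquisition of K phase-delayed images.

    ``images`` has shape (K, H, Z) with axis 1 the vertical (y) image
    axis and axis 2 the axial (z, depth) axis.
    """

    images: np.ndarray
    phases_deg: np.ndarray
    modulation_freq_hz: float
    y_pixel_um: float = 3.0
    z_pixel_um: float = 4.5
    channel: str = "tissue"
    replicate: int = 0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.phases_deg = np.asarray(self.phases_deg, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (K, H, Z) array")
        K = self.images.shape[0]
        if K < 3:
            raise ValueError(f"need at least 3 phase steps, got {K}")
        if self.phases_deg.shape != (K,):
            raise ValueError("phases_deg length must match number of images")
        if np.any(self.phases_deg < 0) or np.any(self.phases_deg >= 180):
            raise ValueError("phase angles must lie in [0, 180) degrees")
        if not self.modulation_freq_hz > 0:
            raise ValueError("modulation_freq_hz must be positive")

    @property
    def n_phases(self) -> int:
        return int(self.images.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]


@dataclass
class LifetimeMap:
    """Per-pixel lifetime fit results for one stack."""

    tau_s: np.ndarray
    amplitude: np.ndarray
    mod_amplitude: np.ndarray
    phi_deg: np.ndarray
    residual_rms: np.ndarray
    valid: np.ndarray
    modulation_freq_hz: float
    y_pixel_um: float = 3.0
    z_pixel_um: float = 4.5
    channel: str = "tissue"
    replicate: int = 0


class PhaseFit(NamedTuple):
    tau_s: float
    amplitude: float
    mod_amplitude: float
    phi_deg: float
    residual_rms: float
    valid: bool


def _design_matrix(phases_deg: np.ndarray) -> np.ndarray:
    th = np.deg2rad(phases_deg)
    return np.column_stack([np.ones_like(th), np.cos(th), np.sin(th)])


def _solve_cosine_fit(X: np.ndarray, I: np.ndarray) -> np.ndarray:
    """Solve the normal equations for each column of I (shape K x N)."""
    G = X.T @ X
    if np.linalg.cond(G) > 1e10:
        raise LifetimeFitError(
            "degenerate phase design (duplicate or collinear phase angles)"
        )
    return np.linalg.solve(G, X.T @ I)


def fit_phase_pixel(intensities, phases_deg, freq_hz: float) -> PhaseFit:
    """Fit a single pixel's phase series; see module docstring for the model.

    Returns a :class:`PhaseFit`; a fitted phase outside the open interval
    (0, 90) degrees (unphysical for a positive lifetime at this
    half-period sampling) yields ``valid=False`` with ``tau_s = nan``
    rather than an exception.
    """
    I = np.asarray(intensities, dtype=float)
    phases = np.asarray(phases_deg, dtype=float)
    if I.ndim != 1 or I.shape != phases.shape:
        raise ValueError("intensities and phases_deg must be matching 1-D arrays")
    if I.size < 3:
        raise LifetimeFitError("need at least 3 phase samples")
    if np.ptp(phases) == 0:
        raise LifetimeFitError("phases must not all be equal")

    X = _design_matrix(phases)
    a, b, c = _solve_cosine_fit(X, I[:, None]).ravel()
    resid = I - X @ np.array([a, b, c])
    rms = float(np.sqrt(np.mean(resid**2)))

    phi = float(np.arctan2(c, b))
    B = float(np.hypot(b, c))
    omega = 2.0 * np.pi * freq_hz
    valid = 0.0 < phi < np.pi / 2 and B > 0
    tau = float(np.tan(phi) / omega) if valid else float("nan")
    return PhaseFit(tau, float(a), B, float(np.rad2deg(phi)), rms, valid)


def estimate_lifetime_map(
    stack: PhaseStack, amplitude_threshold: float = 0.10
) -> LifetimeMap:
    """Apply the cosine-basis lifetime fit to every pixel of a stack.

    Pixels are marked invalid when the fitted DC amplitude falls below
    ``amplitude_threshold`` times the stack's 99th-percentile DC
    amplitude (robust to hot pixels) or when the fitted phase lies
    outside the open interval (0, 90) degrees.
    """
    K, H, Z = stack.images.shape
    X = _design_matrix(stack.phases_deg)
    I = stack.images.reshape(K, H * Z).astype(float)
    coef = _solve_cosine_fit(X, I)
    a, b, c = coef

    resid = I - X @ coef
    rms = np.sqrt(np.mean(resid**2, axis=0)).reshape(H, Z)

    phi = np.arctan2(c, b).reshape(H, Z)
    B = np.hypot(b, c).reshape(H, Z)
    A = a.reshape(H, Z)

    omega = 2.0 * np.pi * stack.modulation_freq_hz
    phase_ok = (phi > 0.0) & (phi < np.pi / 2) & (B > 0)
    ref = np.percentile(A, 99)
    amp_ok = A > amplitude_threshold * ref
    valid = phase_ok & amp_ok

    tau = np.full((H, Z), np.nan)
    tau[phase_ok] = np.tan(phi[phase_ok]) / omega

    return LifetimeMap(
        tau_s=tau,
        amplitude=A,
        mod_amplitude=B,
        phi_deg=np.rad2deg(phi),
        residual_rms=rms,
        valid=valid,
        modulation_freq_hz=stack.modulation_freq_hz,
        y_pixel_um=stack.y_pixel_um,
        z_pixel_um=stack.z_pixel_um,
        channel=stack.channel,
        replicate=stack.replicate,
    )


def modulation_lifetime(lt: LifetimeMap, modulation_depth: float) -> np.ndarray:
    """Diagnostic lifetime from the demodulation ratio, requires known m.

    ``M = B / (A m)`` and ``tau_mod = sqrt(1/M^2 - 1) / omega``.  Under
    the ideal single-harmonic model this equals the phase lifetime; a
    systematic disagreement flags model violations (e.g. background or
    harmonic contamination).
    """
    if not 0 < modulation_depth <= 1:
        raise ValueError("modulation_depth must be in (0, 1]")
    omega = 2.0 * np.pi * lt.modulation_freq_hz
    with np.errstate(divide="ignore", invalid="ignore"):
        M = lt.mod_amplitude / (lt.amplitude * modulation_depth)
        arg = 1.0 / M**2 - 1.0
        tau = np.sqrt(np.clip(arg, 0.0, None)) / omega
    tau[~lt.valid | ~np.isfinite(M) | (M <= 0) | (M > 1)] = np.nan
    return tau
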