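"""Three-layer steady-state oxygen diffusion model of the outer retina.

Oxygen diffuses in one dimension from the choriocapillaris across the
outer retina (50-100% of retinal depth).  The outer retina is split into
three layers by oxygen consumption: layer 1 (photoreceptor outer
segments) and layer 3 (outer nuclear layer) consume negligibly, while
layer 2 (photoreceptor inner segments, dense in mitochondria) consumes
at a constant volumetric rate ``q2``.  At steady state

    Dk * d2P/dx2 = Q(x),   Q = q2 on (x1, x2), 0 elsewhere,

with Dirichlet boundary tensions ``P(0) = pc`` (chorioretinal interface)
and ``P(L) = pl`` (outer/inner retinal boundary) and continuity of both
tension and flux at the internal boundaries.  The solution is piecewise
linear-quadratic-linear; fitting it to a measured tPO2 depth profile
yields the outer retinal consumption rate QO2.

Coordinates here run *from the chorioretinal interface toward the inner
retina* and are expressed as fractions of the outer-retinal thickness
``L`` (x_frac = 0 at the interface, 1 at 50% retinal depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .physiology import default_dk_per_min

__all__ = [
    "ThreeLayerParams",
    "ThreeLayerFit",
    "three_layer_po2",
    "box_averaged_po2",
    "finite_difference_po2",
    "fit_three_layer",
    "mean_qo2",
]

_UM_PER_CM = 1e4


@dataclass(frozen=True)
class ThreeLayerParams:
    """Parameters of the three-layer outer-retinal diffusion model.

    Attributes
    ----------
    pc_mmHg, pl_mmHg
        Oxygen tension at the chorioretinal interface and at the
        outer/inner retinal boundary (50% depth), mmHg.
    x1_frac, x2_frac
        Boundaries of the consuming layer 2 as fractions of the
        outer-retinal thickness, measured from the chorioretinal
        interface; 0 <= x1 < x2 <= 1.
    q2
        Volumetric consumption in layer 2, mL O2 mL^-1 min^-1.
    L_um
        Outer-retinal thickness, micrometers.
    Dk
        Oxygen diffusion x solubility product, mL O2 cm^-1 min^-1 mmHg^-1.
    """

    pc_mmHg: float
    pl_mmHg: float
    x1_frac: float
    x2_frac: float
    q2: float
    L_um: float
    Dk: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x1_frac < self.x2_frac <= 1.0):
            raise ValueError(
                f"layer boundaries must satisfy 0 <= x1 < x2 <= 1, got "
                f"({self.x1_frac}, {self.x2_frac})"
            )
        if self.q2 < 0:
            raise ValueError("q2 must be non-negative")
        if self.pc_mmHg < 0 or self.pl_mmHg < 0:
            raise ValueError("boundary tensions must be non-negative")
        if not self.Dk > 0:
            raise ValueError("Dk must be positive")
        if not self.L_um > 0:
            raise ValueError("L_um must be positive")

    @property
    def qo2(self) -> float:
        """Outer-retina-averaged consumption, mL O2 / 100 g / min.

        Equals ``100 * q2 * (x2 - x1)`` assuming tissue density 1 g/mL:
        consumption in layer 2 spread over the whole outer-retinal depth.
        """
        return 100.0 * self.q2 * (self.x2_frac - self.x1_frac)

    @property
    def curvature_mmHg(self) -> float:
        """Profile curvature q2*L^2/Dk in fractional coordinates, mmHg."""
        L_cm = self.L_um / _UM_PER_CM
        return self.q2 * L_cm**2 / self.Dk


def _segment_coefficients(params: ThreeLayerParams) -> np.ndarray:
    """Solve the linear system for the piecewise segment coefficients.

    Unknowns are (a1, b1, a2, b2, a3, b3) with
    P1 = a1 + b1 x, P2 = a2 + b2 x + (Q/2) x^2, P3 = a3 + b3 x,
    Q = q2 L^2 / Dk the curvature in fractional coordinates.  Equations:
    the two Dirichlet conditions and continuity of tension and flux at
    x1 and x2 (constant Dk makes flux continuity slope continuity).
    """
    x1, x2 = params.x1_frac, params.x2_frac
    Q = params.curvature_mmHg
    A = np.array(
        [
            [1.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # P1(0) = pc
            [0.0, 0.0, 0.0, 0.0, 1.0, 1.0],  # P3(1) = pl
            [1.0, x1, -1.0, -x1, 0.0, 0.0],  # P1(x1) = P2(x1)
            [0.0, 1.0, 0.0, -1.0, 0.0, 0.0],  # P1'(x1) = P2'(x1)
            [0.0, 0.0, 1.0, x2, -1.0, -x2],  # P2(x2) = P3(x2)
            [0.0, 0.0, 0.0, 1.0, 0.0, -1.0],  # P2'(x2) = P3'(x2)
        ]
    )
    rhs = np.array(
        [
            params.pc_mmHg,
            params.pl_mmHg,
            0.5 * Q * x1**2,
            Q * x1,
            -0.5 * Q * x2**2,
            -Q * x2,
        ]
    )
    return np.linalg.solve(A, rhs)


def three_layer_po2(x_frac, params: ThreeLayerParams):
    """Evaluate the closed-form three-layer tension profile.

    Parameters
    ----------
    x_frac : array_like
        Positions in [0, 1]; 0 at the chorioretinal interface, 1 at the
        outer/inner retinal boundary.
    params
        Model parameters.

    Returns
    -------
    ndarray or float
        Oxygen tension in mmHg at each position.
    """
    x = np.asarray(x_frac, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError("x_frac must lie in [0, 1]")
    a1, b1, a2, b2, a3, b3 = _segment_coefficients(params)
    Q = params.curvature_mmHg
    x1, x2 = params.x1_frac, params.x2_frac
    out = np.where(
        x < x1,
        a1 + b1 * x,
        np.where(x <= x2, a2 + b2 * x + 0.5 * Q * x * x, a3 + b3 * x),
    )
    if np.isscalar(x_frac):
        return float(out)
    return out


def finite_difference_po2(params: ThreeLayerParams, n_nodes: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Independent finite-difference solve of the same boundary-value problem.

    Second-order central differences on a uniform grid of ``n_nodes``
    interior nodes.  The piecewise-constant source is sampled by its
    *cell average* over each node's cell so the layer boundaries are
    represented with sub-cell accuracy; pointwise sampling would misplace
    the consumption jumps by up to half a cell and dominate the error.

    Intended as a numerical cross-check of :func:`three_layer_po2`; it
    shares no code with the closed form.

    Returns
    -------
    x : ndarray
        Grid in fractional coordinates, including the boundaries.
    P : ndarray
        Tension at the grid nodes, mmHg.
    """
    Q = params.curvature_mmHg
    x = np.linspace(0.0, 1.0, n_nodes + 2)
    h = x[1] - x[0]
    # cell average of the indicator of (x1, x2) over [xi - h/2, xi + h/2]
    lo = np.clip(x[1:-1] - 0.5 * h, params.x1_frac, params.x2_frac)
    hi = np.clip(x[1:-1] + 0.5 * h, params.x1_frac, params.x2_frac)
    f = Q * (hi - lo) / h

    # tridiagonal system P[i-1] - 2 P[i] + P[i+1] = h^2 f[i]
    from scipy.sparse import diags
    from scipy.sparse.linalg import spsolve

    n = n_nodes
    A = diags([np.ones(n - 1), -2.0 * np.ones(n), np.ones(n - 1)], [-1, 0, 1], format="csc")
    rhs = h * h * f
    rhs[0] -= params.pc_mmHg
    rhs[-1] -= params.pl_mmHg
    P_int = spsolve(A, rhs)
    P = np.concatenate([[params.pc_mmHg], P_int, [params.pl_mmHg]])
    return x, P


@dataclass
class ThreeLayerFit:
    """Result of fitting the three-layer model to one outer depth profile."""

    params: ThreeLayerParams
    qo2_mLO2_per_100g_min: float
    rss: float
    r2: float
    converged: bool
    at_bound: dict = field(default_factory=dict)

    @property
    def usable(self) -> bool:
        """Converged and not pinned at any active constraint."""
        return self.converged and not any(self.at_bound.values())


_BOUNDS_LO = np.array([0.0, 0.0, 0.0, 1e-3, 0.0])
_BOUNDS_HI = np.array([300.0, 300.0, 0.95, 1.0, 10.0])


def _unpack(theta: np.ndarray) -> tuple[float, float, float, float, float]:
    """Map free parameters to (pc, pl, x1, x2, q2); x2 = x1 + (1-x1)*s2."""
    pc, pl, x1, s2, q2 = theta
    x2 = x1 + (1.0 - x1) * s2
    return pc, pl, x1, x2, q2


def _integral_po2(t: np.ndarray, params: ThreeLayerParams) -> np.ndarray:
    """Antiderivative I(t) = int_0^t P~(u) du of the extended profile.

    P~ equals the three-layer solution on [0, 1], continues linearly
    (segment 1) for u < 0 and as the constant boundary tension pl for
    u > 1 (the inner retina beyond the 50% boundary).  Used to evaluate
    moving-window averages of the model analytically.
    """
    a1, b1, a2, b2, a3, b3 = _segment_coefficients(params)
    Q = params.curvature_mmHg
    x1, x2 = params.x1_frac, params.x2_frac

    def seg1(u):
        return a1 * u + 0.5 * b1 * u**2

    def seg2(u):  # cumulative from 0, valid for u in [x1, x2]
        return (
            seg1(x1)
            + a2 * (u - x1)
            + 0.5 * b2 * (u**2 - x1**2)
            + Q / 6.0 * (u**3 - x1**3)
        )

    def seg3(u):  # valid for u in [x2, 1]
        return seg2(x2) + a3 * (u - x2) + 0.5 * b3 * (u**2 - x2**2)

    t = np.asarray(t, dtype=float)
    out = np.where(
        t <= x1,
        seg1(t),
        np.where(t <= x2, seg2(np.minimum(t, x2)), seg3(np.minimum(t, 1.0))),
    )
    return np.where(t > 1.0, seg3(1.0) + params.pl_mmHg * (t - 1.0), out)


def box_averaged_po2(x_frac, params: ThreeLayerParams, window_x: float):
    """Moving-box average of the model profile, window width ``window_x``.

    Models the effect of the axial arm of the anisotropic averaging
    filter on a depth profile: the measured value at x is the mean of
    the true profile over [x - w/2, x + w/2].  Evaluated exactly from
    the piecewise antiderivative; with ``window_x = 0`` this is
    :func:`three_layer_po2`.
    """
    if window_x <= 0:
        return three_layer_po2(x_frac, params)
    x = np.asarray(x_frac, dtype=float)
    h = 0.5 * window_x
    avg = (_integral_po2(x + h, params) - _integral_po2(x - h, params)) / window_x
    if np.isscalar(x_frac):
        return float(avg)
    return avg


def _model_curve(
    theta: np.ndarray, x: np.ndarray, L_um: float, Dk: float, window_x: float = 0.0
) -> np.ndarray:
    pc, pl, x1, x2, q2 = _unpack(theta)
    x2 = min(max(x2, x1 + 1e-6), 1.0)
    p = ThreeLayerParams(pc, pl, x1, x2, q2, L_um, Dk)
    return box_averaged_po2(x, p, window_x)


def fit_three_layer(
    x_frac: Sequence[float],
    tpo2_mmHg: Sequence[float],
    L_um: float,
    Dk: float | None = None,
    init: ThreeLayerParams | None = None,
    n_starts: int = 3,
    seed: int = 0,
    max_iter: int = 500,
    window_x: float = 0.0,
) -> ThreeLayerFit:
    """Fit the three-layer model to an outer-retinal tPO2 profile.

    Non-linear least squares over (pc, pl, x1, x2, q2) with box
    constraints; ``x2`` is parameterized as ``x1 + (1 - x1) * s2`` so the
    ordering constraint stays smooth.  Three jittered restarts (seeded)
    guard against local minima; the best residual wins.

    Parameters
    ----------
    x_frac, tpo2_mmHg
        Profile samples over the outer retina, fractional position from
        the chorioretinal interface (>= 8 samples required).
    L_um
        Outer-retinal thickness of this profile, micrometers.
    Dk
        Diffusion-solubility product (mL O2 cm^-1 min^-1 mmHg^-1);
        defaults to the literature placeholder, with a warning.
    init
        Optional explicit initial parameters.
    window_x
        Width (in fractional units) of a known axial box filter applied
        to the measured profile; when nonzero the *box-averaged* model
        (:func:`box_averaged_po2`) is fit so the estimate is not biased
        by the smoothing of the narrow consuming layer.
    """
    x = np.asarray(x_frac, dtype=float)
    y = np.asarray(tpo2_mmHg, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x_frac and tpo2_mmHg must be matching 1-D arrays")
    if x.size < 8:
        raise ValueError(f"need >= 8 outer-retinal samples, got {x.size}")
    if Dk is None:
        Dk = default_dk_per_min()

    order = np.argsort(x)
    x, y = x[order], y[order]

    if init is not None:
        s2 = (init.x2_frac - init.x1_frac) / max(1.0 - init.x1_frac, 1e-9)
        theta0 = np.array([init.pc_mmHg, init.pl_mmHg, init.x1_frac, s2, init.q2])
    else:
        # pc from the profile maximum (interface side), pl from the sample
        # nearest the 50%-depth end, q2 from the strongest positive discrete
        # curvature (the consuming layer is convex: Dk P'' = q2 >= 0).
        pc0 = float(np.max(y))
        pl0 = float(y[-1])
        d2 = np.gradient(np.gradient(y, x), x)
        L_cm = L_um / _UM_PER_CM
        q20 = max(float(np.max(d2)), 0.0) * Dk / L_cm**2
        theta0 = np.array([pc0, pl0, 0.2, 0.25, q20])
    theta0 = np.clip(theta0, _BOUNDS_LO + 1e-9, _BOUNDS_HI - 1e-9)

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(n_starts - 1, 0)):
        jitter = theta0 * rng.uniform(0.7, 1.3, size=theta0.size)
        jitter[2] = rng.uniform(0.05, 0.5)
        jitter[3] = rng.uniform(0.1, 0.6)
        starts.append(np.clip(jitter, _BOUNDS_LO + 1e-9, _BOUNDS_HI - 1e-9))

    best = None
    for start in starts:
        try:
            res = least_squares(
                lambda th: _model_curve(th, x, L_um, Dk, window_x) - y,
                start,
                bounds=(_BOUNDS_LO, _BOUNDS_HI),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=max_iter * theta0.size,
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        raise RuntimeError("three-layer fit failed from every start")

    pc, pl, x1, x2, q2 = _unpack(best.x)
    x2 = min(max(x2, x1 + 1e-6), 1.0)
    fitted = ThreeLayerParams(pc, pl, x1, x2, q2, L_um, Dk)
    resid = box_averaged_po2(x, fitted, window_x) - y
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    atol = 1e-6 * (_BOUNDS_HI - _BOUNDS_LO)
    names = ("pc", "pl", "x1", "s2", "q2")
    at_bound = {
        nm: bool(best.x[i] - _BOUNDS_LO[i] < atol[i] or _BOUNDS_HI[i] - best.x[i] < atol[i])
        for i, nm in enumerate(names)
    }
    # q2 = 0 is the physically meaningful "no consumption" answer, not an
    # artifact of the box; never treat it as an active constraint.
    at_bound["q2"] = bool(_BOUNDS_HI[4] - best.x[4] < atol[4])

    return ThreeLayerFit(
        params=fitted,
        qo2_mLO2_per_100g_min=fitted.qo2,
        rss=rss,
        r2=r2,
        converged=bool(best.status > 0),
        at_bound=at_bound,
    )


def mean_qo2(fits: Sequence[ThreeLayerFit]) -> tuple[float | None, int]:
    """Average QO2 over usable fits.

    Fits that failed to converge or sat on an active constraint are
    excluded.  Returns ``(mean, n_excluded)``; the mean is ``None`` when
    no fit is usable.
    """
    fits = list(fits)
    usable = [f.qo2_mLO2_per_100g_min for f in fits if f.usable]
    n_excluded = len(fits) - len(usable)
    if not usable:
        return None, n_excluded
    return float(np.mean(usable)), n_excluded
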