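"""Blood oxygen content, inner retinal OEF, and cohort summary statistics.

Oxygen content combines hemoglobin-bound and dissolved oxygen:

    C(PO2) = capacity * S(PO2) + solubility * PO2

with the Hill saturation curve S(PO2) = PO2^n / (PO2^n + P50^n).  The
inner retinal oxygen extraction fraction is the fraction of the oxygen
delivered by the retinal circulation that inner retinal tissue extracts:

    OEF = (C(PO2A) - C(PO2V)) / C(PO2A).

OEF is computed per animal from that animal's mean arterial and venous
tensions and only then averaged across a cohort; the cohort-mean OEF is
therefore not the OEF of the cohort-mean tensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .physiology import DissociationCurve

__all__ = [
    "OefResult",
    "hill_saturation",
    "o2_content",
    "oef",
    "cohort_stats",
]


@dataclass(frozen=True)
class OefResult:
    """Inner retinal oxygen extraction: tensions, saturations, contents."""

    po2a_mmHg: float
    po2v_mmHg: float
    sa: float
    sv: float
    ca: float
    cv: float
    oef: float


def hill_saturation(po2_mmHg, curve: DissociationCurve):
    """Hemoglobin oxygen saturation at ``po2_mmHg`` via the Hill equation."""
    po2 = np.asarray(po2_mmHg, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("PO2 must be non-negative")
    pn = po2**curve.hill_n
    s = pn / (pn + curve.p50_mmHg**curve.hill_n)
    if np.isscalar(po2_mmHg):
        return float(s)
    return s


def o2_content(po2_mmHg, curve: DissociationCurve):
    """Blood oxygen content, mL O2 per mL blood (bound + dissolved)."""
    po2 = np.asarray(po2_mmHg, dtype=float)
    c = curve.hb_capacity * hill_saturation(po2, curve) + curve.solubility * po2
    if np.isscalar(po2_mmHg):
        return float(c)
    return c


def oef(po2a_mmHg: float, po2v_mmHg: float, curve: DissociationCurve) -> OefResult:
    """Inner retinal oxygen extraction fraction from PO2A and PO2V."""
    if not po2a_mmHg > 0:
        raise ValueError("arterial PO2 must be positive")
    if po2v_mmHg < 0:
        raise ValueError("venous PO2 must be non-negative")
    sa = hill_saturation(po2a_mmHg, curve)
    sv = hill_saturation(po2v_mmHg, curve)
    ca = o2_content(po2a_mmHg, curve)
    cv = o2_content(po2v_mmHg, curve)
    if ca == 0:
        raise ZeroDivisionError("arterial oxygen content is zero; OEF undefined")
    return OefResult(
        po2a_mmHg=float(po2a_mmHg),
        po2v_mmHg=float(po2v_mmHg),
        sa=sa,
        sv=sv,
        ca=ca,
        cv=cv,
        oef=(ca - cv) / ca,
    )


_PAIRED = (("po2a", "po2v"), ("po2v", "inner_tpo2"))
_REGRESSIONS = (("max_outer_tpo2", "qo2"), ("inner_tpo2", "oef"))


def cohort_stats(per_animal: pd.DataFrame | Sequence[Mapping]) -> dict:
    """Cohort summary: per-column mean +- SD, paired t-tests, regressions.

    Expects one row per animal with (a subset of) the columns ``po2a``,
    ``po2v``, ``inner_tpo2``, ``max_outer_tpo2``, ``min_outer_tpo2``,
    ``oef``, ``qo2``.  Computes paired two-sided t-tests for
    (po2a, po2v) and (po2v, inner_tpo2) and ordinary least-squares
    regressions (slope, intercept, R^2, p) of qo2 on max_outer_tpo2 and
    oef on inner_tpo2.  Degenerate-variance statistics are reported as
    NaN with ``defined=False``.
    """
    df = pd.DataFrame(per_animal)
    if len(df) < 3:
        raise ValueError(f"need at least 3 animals, got {len(df)}")

    summary: dict = {"n": int(len(df)), "columns": {}, "paired": {}, "regressions": {}}
    for col in df.columns:
        vals = df[col].astype(float)
        summary["columns"][col] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
        }

    for a, b in _PAIRED:
        if a not in df or b not in df:
            continue
        diff = df[a].astype(float) - df[b].astype(float)
        if np.isclose(diff.std(ddof=1), 0.0):
            summary["paired"][f"{a}_vs_{b}"] = {
                "t": 0.0 if np.allclose(diff, 0) else float("nan"),
                "p": float("nan"),
                "defined": bool(np.allclose(diff, 0)),
            }
            continue
        t, p = stats.ttest_rel(df[a], df[b])
        summary["paired"][f"{a}_vs_{b}"] = {"t": float(t), "p": float(p), "defined": True}

    for x, y in _REGRESSIONS:
        if x not in df or y not in df:
            continue
        xv = df[x].astype(float).to_numpy()
        yv = df[y].astype(float).to_numpy()
        if np.isclose(np.std(xv), 0.0):
            summary["regressions"][f"{y}_vs_{x}"] = {
                "slope": float("nan"),
                "intercept": float("nan"),
                "r2": float("nan"),
                "p": float("nan"),
                "defined": False,
            }
            continue
        res = stats.linregress(xv, yv)
        summary["regressions"][f"{y}_vs_{x}"] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r2": float(res.rvalue**2),
            "p": float(res.pvalue),
            "defined": True,
        }
    return summary
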