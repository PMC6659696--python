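"""Cell-division orientation from midbody / daughter-separation segments.

A division event is a pair of surface endpoints in ``(s, phi)`` coordinates
(the positions of the two daughters or midbody flanks).  The reported angle
is that of the division *axis* relative to the latitudinal direction, folded
into [0°, 90°] (0° = latitudinal, 90° = meridional / A–P); the cytokinesis
plane is perpendicular to this axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .surface import SurfaceParam

__all__ = ["DivisionEvent", "division_angle", "angle_summary", "events_to_frame"]


@dataclass
class DivisionEvent:
    s1: float
    phi1: float
    s2: float
    phi2: float
    stage_group: str | None = None   # e.g. "3-4" or "5-6"
    angle: float | None = None       # degrees [0, 90], filled by division_angle

    def __post_init__(self) -> None:
        if self.s1 == self.s2 and np.isclose(
            np.mod(self.phi1 - self.phi2, 2 * np.pi), 0.0
        ):
            raise ValueError("division endpoints are coincident")


def _wrap_dphi(dphi: float) -> float:
    return (dphi + np.pi) % (2 * np.pi) - np.pi


def division_angle(event: DivisionEvent, param: SurfaceParam) -> float:
    """Axis angle of a division segment, degrees in [0, 90].

    The endpoint displacement is expressed in the locally orthonormal frame
    at the segment midpoint: arc-length change along the meridian versus
    ``rho · Δphi`` along the latitude.
    """
    ds = event.s2 - event.s1
    dphi = _wrap_dphi(event.phi2 - event.phi1)
    s_mid = 0.5 * (event.s1 + event.s2)
    rho = float(param.rho_profile(s_mid))
    dlat = rho * dphi
    if abs(ds) < 1e-12 and abs(dlat) < 1e-12:
        raise ValueError("division endpoints are coincident on the surface")
    ang = np.degrees(np.arctan2(abs(ds), abs(dlat)))
    event.angle = float(ang)
    return float(ang)


def angle_summary(
    events,
    param: SurfaceParam,
    n_bins: int = 9,
    n_reference: int = 10000,
) -> dict:
    """Histogram over [0°, 90°] plus a uniformity statistic.

    Angles are pooled across events; uniformity is reported as a two-sample
    Kolmogorov–Smirnov test against a deterministic uniform reference sample
    (evenly spaced quantiles of U[0, 90]).
    """
    events = list(events)
    if len(events) == 0:
        raise ValueError("no division events provided")
    if len(events) < 5:
        raise ValueError(f"need >= 5 events for a summary (got {len(events)})")
    angles = np.array([division_angle(ev, param) for ev in events])
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    hist, _ = np.histogram(angles, bins=edges)
    frac = hist / hist.sum()
    reference = (np.arange(n_reference) + 0.5) / n_reference * 90.0
    ks = stats.ks_2samp(angles, reference, method="asymp")
    return {
        "angles": angles,
        "bin_edges": edges,
        "bin_fractions": frac,
        "mean_angle": float(angles.mean()),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n": len(angles),
    }


def events_to_frame(events, param: SurfaceParam | None = None) -> pd.DataFrame:
    """Tabulate events as CSV-ready rows (s1, phi1, s2, phi2, stage, angle)."""
    rows = []
    for ev in events:
        ang = ev.angle
        if ang is None and param is not None:
            ang = division_angle(ev, param)
        rows.append({
            "s1": ev.s1, "phi1": ev.phi1, "s2": ev.s2, "phi2": ev.phi2,
            "stage": ev.stage_group, "angle_deg": ang,
        })
    return pd.DataFrame(rows)
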