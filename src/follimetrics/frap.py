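"""FRAP normalization and one-phase association fitting.

The raw channels of a photobleaching experiment — bleached ROI ``Y_BL``,
reference ROI ``Y_REF`` and background ``Y_BG``, plus their pre-bleach
scalars — are double-normalized to correct both background and acquisition
photobleaching:

    Y(t) = (Y_BL(t) − Y_BG(t)) / (Y_REF(t) − Y_BG(t))
           × (Y_REF0 − Y_BG0) / (Y_PRE − Y_BG0)

The normalized recovery is fitted by unweighted nonlinear least squares to
the one-phase association model

    f(t) = Y0 + (P − Y0) (1 − exp(−K t))

with half-time ln(2)/K and mobile fraction P − Y0.  t = 0 is the first
post-bleach frame; pre-bleach frames enter only through the scalars
(averaged when multiple).  95% confidence intervals come from the parameter
covariance at the optimum (t-quantile × standard error; delta method for the
derived half-time and mobile fraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["FrapTrace", "FrapFit", "normalize_trace", "fit_recovery", "read_trace_csv"]


@dataclass
class FrapTrace:
    """Raw FRAP channels; time in seconds post-bleach (t[0] = 0 allowed)."""

    t: np.ndarray
    y_bl: np.ndarray
    y_ref: np.ndarray
    y_bg: np.ndarray
    y_pre: float    # pre-bleach bleached-ROI intensity
    y_ref0: float   # pre-bleach reference intensity
    y_bg0: float    # pre-bleach background intensity

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y_bl = np.asarray(self.y_bl, dtype=float)
        self.y_ref = np.asarray(self.y_ref, dtype=float)
        self.y_bg = np.asarray(self.y_bg, dtype=float)
        n = len(self.t)
        if not (len(self.y_bl) == len(self.y_ref) == len(self.y_bg) == n):
            raise ValueError("channel lengths differ")
        if self.y_pre - self.y_bg0 <= 0:
            raise ValueError("pre-bleach intensity must exceed background")


@dataclass
class FrapFit:
    Y0: float
    P: float
    K: float
    half_time: float
    mobile_fraction: float
    ci_Y0: tuple
    ci_P: tuple
    ci_K: tuple
    ci_half_time: tuple
    ci_mobile_fraction: tuple
    n_points: int
    residual_sd: float


def normalize_trace(trace: FrapTrace) -> np.ndarray:
    """Double-normalized recovery Y(t); exact per-time-point evaluation."""
    denom = trace.y_ref - trace.y_bg
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise ValueError(
            f"reference does not exceed background at time indices {bad[:5].tolist()}"
        )
    pre = trace.y_pre - trace.y_bg0
    ref0 = trace.y_ref0 - trace.y_bg0
    return (trace.y_bl - trace.y_bg) / denom * (ref0 / pre)


def one_phase_association(t, Y0, P, K):
    return Y0 + (P - Y0) * (1.0 - np.exp(-K * t))


def _init_guess(t, y):
    y0 = float(y[0])
    tail = max(1, len(y) // 10)
    p = float(np.mean(y[-tail:]))
    # log-linear regression of the residual amplitude for K
    amp = p - y
    denom = p - y0
    k = 0.05
    if denom > 1e-9:
        frac = amp / denom
        ok = (frac > 1e-3) & (t > 0)
        if np.count_nonzero(ok) >= 3:
            slope = np.polyfit(t[ok], np.log(frac[ok]), 1)[0]
            if slope < 0:
                k = float(-slope)
    return y0, p, float(np.clip(k, 1e-4, 9.9))


def fit_recovery(t, y, confidence: float = 0.95) -> FrapFit:
    """Nonlinear least-squares fit of the one-phase association model.

    Bounds: Y0 ∈ [0, 1.2], P ∈ [0, 1.5], K ∈ (0, 10].  Raises on fewer than
    10 post-bleach points or non-monotone time; warns (via RuntimeError from
    the optimizer) on non-convergence after bounded restarts.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 10:
        raise ValueError("need >= 10 post-bleach points to fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    p0 = _init_guess(t, y)
    bounds = ([0.0, 0.0, 1e-6], [1.2, 1.5, 10.0])
    last_err = None
    for attempt, guess in enumerate([p0, (0.2, 0.8, 0.02), (0.5, 1.0, 0.1)]):
        try:
            popt, pcov = optimize.curve_fit(
                one_phase_association, t, y,
                p0=np.clip(guess, bounds[0], bounds[1]),
                bounds=bounds, maxfev=20000,
            )
            break
        except RuntimeError as err:  # pragma: no cover - rare
            last_err = err
    else:  # pragma: no cover
        raise RuntimeError(f"FRAP fit did not converge: {last_err}")
    y0, p, k = (float(v) for v in popt)
    if k >= 9.99 or k <= 2e-6:
        import warnings

        warnings.warn(f"rate constant K = {k:.3g} hit the fit bounds", stacklevel=2)
    dof = max(1, len(t) - 3)
    resid = y - one_phase_association(t, *popt)
    sd = float(np.sqrt(resid @ resid / dof))
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    tq = stats.t.ppf(0.5 + confidence / 2, dof)

    def ci(val, s):
        return (val - tq * s, val + tq * s)

    half = float(np.log(2) / k)
    se_half = np.log(2) / k**2 * se[2]
    var_mob = pcov[1, 1] + pcov[0, 0] - 2 * pcov[0, 1]
    se_mob = float(np.sqrt(max(var_mob, 0.0)))
    return FrapFit(
        Y0=y0, P=p, K=k,
        half_time=half,
        mobile_fraction=p - y0,
        ci_Y0=ci(y0, se[0]),
        ci_P=ci(p, se[1]),
        ci_K=ci(k, se[2]),
        ci_half_time=ci(half, se_half),
        ci_mobile_fraction=ci(p - y0, se_mob),
        n_points=len(t),
        residual_sd=sd,
    )


def fit_trace(trace: FrapTrace, confidence: float = 0.95) -> FrapFit:
    """Convenience: normalize then fit."""
    return fit_recovery(trace.t, normalize_trace(trace), confidence=confidence)


def read_trace_csv(path) -> FrapTrace:
    """Read a trace CSV with columns time_s, bleach, reference, background.

    Rows with negative ``time_s`` are pre-bleach frames and are averaged into
    the pre-bleach scalars.
    """
    df = pd.read_csv(path)
    need = {"time_s", "bleach", "reference", "background"}
    if not need.issubset(df.columns):
        raise ValueError(f"trace CSV must have columns {sorted(need)}")
    pre = df[df["time_s"] < 0]
    post = df[df["time_s"] >= 0]
    if len(pre) == 0:
        raise ValueError("trace CSV has no pre-bleach rows (time_s < 0)")
    return FrapTrace(
        t=post["time_s"].to_numpy(),
        y_bl=post["bleach"].to_numpy(),
        y_ref=post["reference"].to_numpy(),
        y_bg=post["background"].to_numpy(),
        y_pre=float(pre["bleach"].mean()),
        y_ref0=float(pre["reference"].mean()),
        y_bg0=float(pre["background"].mean()),
    )
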