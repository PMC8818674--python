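"""Windowed normalizations, difference bands, and the I-P half-time fit.

Relative variable fluorescence rescales a stretch of the OJIP rise between
two reference levels so that physiologically matched curves coincide:

- V_OP on [50 us, t(F_M)] between Fo and F_M,
- V_OK on [50, 300] us between Fo and F_K (the L-band window),
- V_OJ on [50 us, 2 ms] between Fo and F_J (the K-band window),
- V_OI on [50 us, 30 ms] between Fo and F_I,
- V_IP on [30, 180] ms between F_I and F_M.

Subtracting the control curve from the treated curve on a shared log-time
grid gives the difference bands: a negative bell around ~150 us (L-band)
reports loss of antenna-PSII energetic connectivity, a positive band around
~300 us (K-band) reports donor-side/OEC limitation.

The V_IP rise is summarized by a Michaelis-Menten (rectangular hyperbola)
fit v(t') = vmax * t' / (Km + t') with the time origin shifted to the
I step (30 ms); Km is then the half-time of PSI end-acceptor reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ojipnet.transients import FluorescenceTransient, log_grid, value_at, values_at
from ojipnet.jip import extract_cardinal_points, T_O, T_K, T_J, T_I

logger = logging.getLogger(__name__)

CURVE_KINDS = ("V_OP", "V_OK", "V_OJ", "V_OI", "V_IP")

#: V_IP window, us
T_IP_START, T_IP_END = 30_000.0, 180_000.0


class DegenerateCurveError(ValueError):
    """The normalization denominator is zero (flat segment)."""


@dataclass(frozen=True)
class NormalizedCurve:
    """Relative variable fluorescence of one kind on its window."""

    kind: str
    window_us: tuple[float, float]
    time_us: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if len(self.time_us) != len(self.v):
            raise ValueError("time and value arrays differ in length")


@dataclass(frozen=True)
class DeltaBand:
    """Treated-minus-control difference kinetics on a shared grid.

    ``peak_value`` is signed; its magnitude is the largest |dv| on the
    window and ``peak_time_us`` its location (first occurrence on ties).
    """

    kind: str
    time_us: np.ndarray
    dv: np.ndarray
    peak_time_us: float
    peak_value: float


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten fit of the V_IP rise.

    ``km_ms`` is the half-saturation time on the I-origin-shifted axis,
    i.e. the time after the 30-ms I step at which half the fitted
    asymptote ``vmax`` is reached.
    """

    km_ms: float
    vmax: float
    rss: float
    converged: bool
    message: str = ""


def _window_and_refs(
    tr: FluorescenceTransient, kind: str, voi_upper_us: float
) -> tuple[tuple[float, float], float, float]:
    cp = extract_cardinal_points(tr)
    if kind == "V_OP":
        return (T_O, cp.tfm_us), cp.fo, cp.fm
    if kind == "V_OK":
        return (T_O, T_K), cp.fo, cp.f300us
    if kind == "V_OJ":
        return (T_O, T_J), cp.fo, cp.f2ms
    if kind == "V_OI":
        return (T_O, voi_upper_us), cp.fo, cp.f30ms
    if kind == "V_IP":
        return (T_IP_START, T_IP_END), cp.f30ms, cp.fm
    raise ValueError(f"unknown curve kind {kind!r}")


def relative_variable_fluorescence(
    tr: FluorescenceTransient,
    kind: str,
    points_per_decade: int = 60,
    voi_upper_us: float = T_I,
) -> NormalizedCurve:
    """Compute one of the five windowed normalizations on a log grid.

    Window endpoints map exactly onto v = 0 and (for the O-anchored kinds)
    v = 1; V_IP reaches 1 where F equals F_M.  ``voi_upper_us`` makes the
    V_OI upper bound configurable (default: the 30-ms I step).
    """
    window, f_lo, f_hi = _window_and_refs(tr, kind, voi_upper_us)
    denom = f_hi - f_lo
    if denom == 0:
        raise DegenerateCurveError(
            f"{tr.sample_id}: zero denominator for {kind} on {window}"
        )
    grid = log_grid(window[0], window[1], points_per_decade)
    v = (values_at(tr, grid) - f_lo) / denom
    # pin the anchor endpoints exactly (interpolation is exact there anyway,
    # up to floating round-off)
    v[0] = (value_at(tr, window[0]) - f_lo) / denom
    return NormalizedCurve(kind=kind, window_us=window, time_us=grid, v=v)


def mean_curve(curves: Sequence[NormalizedCurve], points_per_decade: int = 60) -> NormalizedCurve:
    """Replicate-mean curve on a shared log grid over the common window."""
    if not curves:
        raise ValueError("no curves to average")
    kinds = {c.kind for c in curves}
    if len(kinds) != 1:
        raise ValueError(f"mixed curve kinds: {sorted(kinds)}")
    lo = max(c.window_us[0] for c in curves)
    hi = min(c.window_us[1] for c in curves)
    grid = log_grid(lo, hi, points_per_decade)
    stack = np.stack(
        [np.interp(np.log10(grid), np.log10(c.time_us), c.v) for c in curves]
    )
    return NormalizedCurve(
        kind=curves[0].kind, window_us=(lo, hi), time_us=grid, v=stack.mean(axis=0)
    )


def delta_band(
    treated: NormalizedCurve,
    control: NormalizedCurve,
    points_per_decade: int = 60,
) -> DeltaBand:
    """Pointwise treated-minus-control difference on a shared log grid.

    The extremum of largest magnitude is reported with its sign (a
    negative bell shape at ~150 us is the L-band signature; a positive band
    at ~300 us the K-band signature).
    """
    if treated.kind != control.kind:
        raise ValueError(
            f"kind mismatch: {treated.kind} vs {control.kind}"
        )
    lo = max(treated.window_us[0], control.window_us[0])
    hi = min(treated.window_us[1], control.window_us[1])
    grid = log_grid(lo, hi, points_per_decade)
    vt = np.interp(np.log10(grid), np.log10(treated.time_us), treated.v)
    vc = np.interp(np.log10(grid), np.log10(control.time_us), control.v)
    dv = vt - vc
    i_peak = int(np.argmax(np.abs(dv)))
    return DeltaBand(
        kind=treated.kind,
        time_us=grid,
        dv=dv,
        peak_time_us=float(grid[i_peak]),
        peak_value=float(dv[i_peak]),
    )


def _mm_residuals(params: np.ndarray, t: np.ndarray, v: np.ndarray) -> np.ndarray:
    vmax, km = params
    return vmax * t / (km + t) - v


def fit_vip_mm(curve: NormalizedCurve, origin_us: float = T_IP_START) -> MMFit:
    """Least-squares Michaelis-Menten fit of a V_IP curve.

    The time axis is shifted so t' = 0 at the I step (``origin_us``,
    default 30 ms) and expressed in ms.  Initialisation is deterministic:
    vmax starts at 1 and Km at the observed half-rise time, with a fixed
    ladder of fallback starts; the best residual sum of squares wins.
    Non-convergence (including unidentifiable flat curves) is reported via
    ``converged=False``, never an exception.
    """
    if curve.kind != "V_IP":
        raise ValueError(f"expected a V_IP curve, got {curve.kind}")
    t_ms = (curve.time_us - origin_us) / 1_000.0
    keep = t_ms >= 0
    t = t_ms[keep]
    v = curve.v[keep]
    if t.size < 6:
        return MMFit(np.nan, np.nan, np.nan, False, "fewer than 6 points")
    if np.ptp(v) < 1e-12:
        return MMFit(np.nan, np.nan, np.nan, False, "flat curve: Km unidentifiable")

    # deterministic multi-start: half-rise crossing plus a fixed ladder
    v_half = 0.5 * (v[0] + v[-1] if v[-1] > v[0] else 1.0)
    above = np.nonzero(v >= v_half)[0]
    km_starts = [10.0, 50.0, 150.0]
    if above.size and above[0] > 0:
        km_starts.insert(0, float(t[above[0]]))

    best = None
    for km0 in km_starts:
        if km0 <= 0:
            continue
        res = least_squares(
            _mm_residuals,
            x0=np.array([1.0, km0]),
            args=(t, v),
            bounds=([0.0, 1e-9], [np.inf, np.inf]),
            method="trf",
        )
        rss = float(np.sum(res.fun**2))
        if res.success and (best is None or rss < best[0]):
            best = (rss, res)
    if best is None:
        return MMFit(np.nan, np.nan, np.nan, False, "optimizer did not converge")
    rss, res = best
    vmax, km = (float(x) for x in res.x)
    if km <= 1e-6:
        return MMFit(km, vmax, rss, False, "Km collapsed to zero (degenerate rise)")
    return MMFit(km_ms=km, vmax=vmax, rss=rss, converged=True)
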