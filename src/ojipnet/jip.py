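"""Cardinal-point extraction and the JIP-test parameter suite.

The JIP-test reduces a polyphasic OJIP transient to a handful of landmark
intensities — F at 50 us (Fo, the O level), 300 us (K), 2 ms (J), 30 ms (I)
and the peak F_M (P) — and derives from them quantum yields, specific
(per-reaction-centre) and phenomenological (per-cross-section) energy
fluxes, pool sizes and performance indices.

Conventions used here (each is the standard JIP-test choice):

- Fo is F at 50 us; every normalization starts there.
- Mo, the initial slope of the relative variable fluorescence rise, is
  4 * (F300us - Fo) / (F_M - Fo) per ms.
- ABS/CS is approximated by F_M (hence the "CSm" suffix on the
  phenomenological fluxes); the de-excitation constants Kp and Kn use the
  same scale:  Kp = ABS/CSm * (1/Fo - 1/F_M),  Kn = ABS/CSm / F_M.
- The complementary area is integrated on the native grid, in linear time,
  between 50 us and the time of F_M, giving Sm = area / (F_M - Fo) in units
  of the J-step turnover.

Degenerate inputs (F_M <= Fo, or V_J in {0, 1}) yield NaN for the affected
ratios together with an explanatory flag, never a silent infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from ojipnet.transients import (
    FluorescenceTransient,
    TransientSet,
    value_at,
)

#: cardinal times, us
T_O, T_100, T_K, T_J, T_I = 50.0, 100.0, 300.0, 2_000.0, 30_000.0

#: the five phenomenological (per-cross-section) fluxes
CS_FLUXES = ["abs_csm", "tro_csm", "eto_csm", "dio_csm", "rc_csm"]


class InternalConsistencyError(AssertionError):
    """A conservation identity failed beyond numerical tolerance."""


@dataclass(frozen=True)
class CardinalPoints:
    """O/K/J/I/P landmark intensities of one transient.

    ``area_ms`` is the complementary area integral(F_M - F(t)) dt from
    50 us to ``tfm_us``, in intensity*ms.  ``truncated`` flags a curve whose
    maximum sits on the last sample (the P phase may be cut off).
    """

    fo: float
    f100us: float
    f300us: float
    f2ms: float
    f30ms: float
    fm: float
    tfm_us: float
    area_ms: float
    truncated: bool = False

    def __post_init__(self) -> None:
        steps = (self.fo, self.f100us, self.f300us, self.f2ms, self.f30ms)
        if any(self.fm < s - 1e-9 * abs(self.fm) for s in steps):
            raise ValueError("F_M must be >= every step value")
        if self.area_ms < 0:
            raise ValueError("complementary area must be >= 0")


def extract_cardinal_points(tr: FluorescenceTransient) -> CardinalPoints:
    """Extract the cardinal points of a transient covering [50 us, 300 ms].

    Step values are read by log-time interpolation at 50/100/300 us and
    2/30 ms.  F_M is the curve maximum, with ties resolved to the earliest
    time.  The complementary area uses the trapezoid rule on the native
    grid restricted to [50 us, tfm].
    """
    if not tr.covers(T_O, 300_000.0):
        raise ValueError(
            f"{tr.sample_id}: transient must cover [50 us, 300 ms], "
            f"got [{tr.time_us[0]}, {tr.time_us[-1]}] us"
        )
    steps = [value_at(tr, t) for t in (T_O, T_100, T_K, T_J, T_I)]
    i_max = int(np.argmax(tr.f))  # argmax takes the first of equal maxima
    fm = float(tr.f[i_max])
    tfm_us = float(tr.time_us[i_max])
    truncated = i_max == len(tr) - 1

    # complementary area on [50 us, tfm], native grid + exact 50-us anchor
    mask = (tr.time_us > T_O) & (tr.time_us <= tfm_us)
    t_grid = np.concatenate(([T_O], tr.time_us[mask]))
    f_grid = np.concatenate(([steps[0]], tr.f[mask]))
    area_ms = float(np.trapezoid(fm - f_grid, t_grid) / 1_000.0)

    return CardinalPoints(
        fo=steps[0],
        f100us=steps[1],
        f300us=steps[2],
        f2ms=steps[3],
        f30ms=steps[4],
        fm=fm,
        tfm_us=tfm_us,
        area_ms=max(area_ms, 0.0),
        truncated=truncated,
    )


@dataclass(frozen=True)
class JipParameterSet:
    """The derived JIP-test parameter vector of one transient.

    Yield-type quantities (phi_po = Fv/Fm, phi_do, psi_eo, phi_eo, delta_ro)
    are dimensionless fractions; RC-normalized fluxes are per reaction
    centre; CSm-normalized fluxes are on the F_M intensity scale; mo is in
    1/ms and sm/n_turnover are turnover counts.  ``flags`` collects
    degeneracy markers; flagged quantities are NaN.
    """

    vj: float
    vi: float
    mo: float
    fv_fm: float
    fv_fo: float
    fo_fm: float
    psi_eo: float
    phi_eo: float
    delta_ro: float
    reo_abs: float
    reo_eto: float
    sm: float
    n_turnover: float
    abs_rc: float
    tro_rc: float
    eto_rc: float
    dio_rc: float
    pi_abs: float
    sfi_abs: float
    df: float
    abs_csm: float
    tro_csm: float
    eto_csm: float
    dio_csm: float
    rc_csm: float
    pi_csm: float
    kp: float
    kn: float
    sum_k: float
    sm_tfm: float
    phio_ratio: float
    psio_ratio: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in dc_fields(self)
            if f.name != "flags"
        }


#: parameter names in the canonical export order
PARAMETER_NAMES = [f.name for f in dc_fields(JipParameterSet) if f.name != "flags"]

_NAN = float("nan")


def compute_jip_parameters(cp: CardinalPoints) -> JipParameterSet:
    """Derive the full JIP-test parameter suite from cardinal points.

    With Fv = F_M - Fo:  phi_po = Fv/F_M, V_J = (F_2ms - Fo)/Fv,
    Mo = 4 (F_300us - Fo)/Fv per ms, psi_Eo = 1 - V_J, and so on through the
    specific fluxes (TRo/RC = Mo/V_J, ABS/RC = TRo/RC / phi_po, ...),
    performance indices and per-cross-section fluxes (ABS/CSm = F_M).
    """
    flags: set[str] = set()
    fo, fm = cp.fo, cp.fm
    fv = fm - fo

    if fv <= 0:
        # photochemistry-free: no variable fluorescence at all
        flags.add("degenerate_fm_le_fo")
        nan_kwargs = {
            name: _NAN
            for name in PARAMETER_NAMES
            if name not in {"fv_fm", "fo_fm", "abs_csm"}
        }
        return JipParameterSet(
            fv_fm=0.0,
            fo_fm=1.0,
            abs_csm=fm,
            flags=frozenset(flags),
            **nan_kwargs,
        )

    vj = (cp.f2ms - fo) / fv
    vi = (cp.f30ms - fo) / fv
    mo = 4.0 * (cp.f300us - fo) / fv  # per ms
    phi_po = 1.0 - fo / fm
    phi_do = fo / fm
    psi_eo = 1.0 - vj
    phi_eo = phi_po * psi_eo
    sm = cp.area_ms / fv
    tfm_ms = cp.tfm_us / 1_000.0

    vj_degenerate = not (0.0 < vj < 1.0)
    mo_zero = mo == 0.0
    if vj_degenerate:
        flags.add("degenerate_vj")
    if mo_zero:
        flags.add("degenerate_mo_zero")

    if vj_degenerate or mo_zero:
        delta_ro = reo_eto = n_turnover = tro_rc = abs_rc = _NAN
        eto_rc = dio_rc = pi_abs = sfi_abs = df_ = rc_csm = pi_csm = _NAN
        psio_ratio = _NAN
    else:
        delta_ro = (1.0 - vi) / (1.0 - vj)
        reo_eto = delta_ro
        n_turnover = sm * mo / vj
        tro_rc = mo / vj
        abs_rc = tro_rc / phi_po
        eto_rc = tro_rc * psi_eo
        dio_rc = abs_rc - tro_rc
        rc_abs = phi_po * vj / mo
        pi_abs = rc_abs * (phi_po / (1.0 - phi_po)) * (psi_eo / (1.0 - psi_eo))
        sfi_abs = rc_abs * phi_po * psi_eo
        df_ = math.log10(pi_abs) if pi_abs > 0 else _NAN
        rc_csm = rc_abs * fm
        pi_csm = pi_abs * fm
        psio_ratio = psi_eo / vj

    abs_csm = fm
    kp = abs_csm * (1.0 / fo - 1.0 / fm)
    kn = abs_csm * (1.0 / fm)

    return JipParameterSet(
        vj=vj,
        vi=vi,
        mo=mo,
        fv_fm=phi_po,
        fv_fo=fv / fo,
        fo_fm=phi_do,
        psi_eo=psi_eo,
        phi_eo=phi_eo,
        delta_ro=delta_ro,
        reo_abs=phi_po * (1.0 - vi),
        reo_eto=reo_eto,
        sm=sm,
        n_turnover=n_turnover,
        abs_rc=abs_rc,
        tro_rc=tro_rc,
        eto_rc=eto_rc,
        dio_rc=dio_rc,
        pi_abs=pi_abs,
        sfi_abs=sfi_abs,
        df=df_,
        abs_csm=abs_csm,
        tro_csm=phi_po * fm,
        eto_csm=phi_eo * fm,
        dio_csm=(1.0 - phi_po) * fm,
        rc_csm=rc_csm,
        pi_csm=pi_csm,
        kp=kp,
        kn=kn,
        sum_k=kp + kn,
        sm_tfm=sm / tfm_ms,
        phio_ratio=phi_po / phi_do,
        psio_ratio=psio_ratio,
        flags=frozenset(flags),
    )


def jip_parameters_for(tr: FluorescenceTransient) -> JipParameterSet:
    """Convenience: extract cardinal points and derive all parameters."""
    return compute_jip_parameters(extract_cardinal_points(tr))


def summarize_group(ts: TransientSet) -> pd.DataFrame:
    """Per-group mean +/- SD of every JIP parameter.

    Returns a tidy frame with one row per (treatment, timepoint_days,
    parameter); SD is the sample standard deviation (ddof=1), reported as
    NaN for singleton groups.
    """
    rows = []
    for (treatment, timepoint), members in ts.groups().items():
        vectors = pd.DataFrame(
            [jip_parameters_for(tr).as_dict() for tr in members]
        )
        n = len(members)
        for name in PARAMETER_NAMES:
            vals = vectors[name].to_numpy()
            rows.append(
                {
                    "treatment": treatment,
                    "timepoint_days": timepoint,
                    "parameter": name,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if n >= 2 else _NAN,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def normalize_to_control(
    treated_summary: pd.DataFrame, control_summary: pd.DataFrame
) -> pd.DataFrame:
    """Ratio of treated to control group means per parameter (radar table).

    Both inputs are summaries in the :func:`summarize_group` layout (one
    treatment/timepoint each).  A control mean of zero yields NaN with an
    ``undefined`` marker instead of infinity.
    """
    t = treated_summary.set_index("parameter")["mean"]
    c = control_summary.set_index("parameter")["mean"]
    if set(t.index) != set(c.index):
        raise ValueError("parameter sets differ between treated and control")
    c = c.reindex(t.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = t / c
    ratio[c == 0] = np.nan
    out = pd.DataFrame(
        {
            "parameter": t.index,
            "treated_mean": t.to_numpy(),
            "control_mean": c.to_numpy(),
            "ratio_to_control": ratio.to_numpy(),
        }
    )
    out["undefined"] = (c == 0).to_numpy()
    return out.reset_index(drop=True)


def ratio_table(
    summary: pd.DataFrame, control_treatment: str = "control"
) -> pd.DataFrame:
    """Control-normalized ratios for every non-control group in a summary.

    Controls are matched by timepoint; the control group's own ratios are 1
    by construction.
    """
    frames = []
    for timepoint, sub in summary.groupby("timepoint_days"):
        control = sub[sub["treatment"] == control_treatment]
        if control.empty:
            raise ValueError(
                f"no control group ({control_treatment!r}) at timepoint {timepoint}"
            )
        for treatment, tsub in sub.groupby("treatment"):
            r = normalize_to_control(tsub, control)
            r.insert(0, "treatment", treatment)
            r.insert(1, "timepoint_days", timepoint)
            frames.append(r)
    return pd.concat(frames, ignore_index=True)


def pipeline_flux_table(
    summary: pd.DataFrame, control_treatment: str = "control", atol: float = 1e-9
) -> pd.DataFrame:
    """Leaf energy-pipeline table: the five per-CS fluxes with control ratios.

    Asserts the energy balance ABS/CSm = TRo/CSm + DIo/CSm on every group
    (means are linear, so the identity survives averaging).
    """
    cs = summary[summary["parameter"].isin(CS_FLUXES)]
    wide = cs.pivot_table(
        index=["treatment", "timepoint_days"], columns="parameter", values="mean"
    )
    imbalance = np.abs(wide["abs_csm"] - (wide["tro_csm"] + wide["dio_csm"]))
    bad = imbalance > atol * np.maximum(np.abs(wide["abs_csm"]), 1.0)
    if bad.any():
        raise InternalConsistencyError(
            f"ABS/CSm != TRo/CSm + DIo/CSm for groups {list(wide.index[bad])}"
        )
    out = ratio_table(cs, control_treatment=control_treatment)
    return out
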