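"""Gas-exchange derived metrics and the study's inferential statistics.

Provides instantaneous water-use efficiency (WUE_i = A_sat / E), signed
percent change relative to control, the classical pooled-variance two-sample
t-test, and a balanced fixed-effects two-way ANOVA with interaction — the
latter two written out from their closed forms so the sums-of-squares
decomposition is explicit and auditable.

Significance stars follow the usual legend: ns (p >= 0.05), * (p < 0.05),
** (p < 0.01), *** (p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_LEGEND = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cut, stars in STAR_LEGEND:
        if p < cut:
            return stars
    return "ns"


def compute_wue(a_sat, e):
    """Instantaneous water-use efficiency A_sat / E (umol CO2 per mmol H2O).

    Accepts scalars or arrays (elementwise).  Transpiration must be
    strictly positive.
    """
    a = np.asarray(a_sat, dtype=float)
    ev = np.asarray(e, dtype=float)
    if np.any(ev <= 0):
        raise ValueError("transpiration rate E must be > 0 for WUE")
    out = a / ev
    return float(out) if out.ndim == 0 else out


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Signed percent change of treated relative to control."""
    if control_mean == 0:
        raise ValueError("control mean must be nonzero for percent change")
    return 100.0 * (treated_mean - control_mean) / control_mean


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def students_t_test(x, y) -> TTestResult:
    """Two-sample two-sided Student's t-test with pooled variance.

    t = (mean(x) - mean(y)) / (s_p * sqrt(1/n + 1/m)) with the pooled
    variance s_p^2 on n + m - 2 degrees of freedom.  A zero pooled variance
    is degenerate: p = 1 for equal means, p -> 0 (t infinite) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise ValueError("each sample needs n >= 2")
    df = n + m - 2
    sp2 = ((n - 1) * x.var(ddof=1) + (m - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        return TTestResult(
            t=float(np.sign(diff)) * float("inf"), df=df, p=0.0, degenerate=True
        )
    t = diff / np.sqrt(sp2 * (1.0 / n + 1.0 / m))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects two-way ANOVA table for a balanced design.

    ``table`` has one row per effect (factor_a, factor_b, interaction,
    residual, total) with sum of squares, degrees of freedom, mean square,
    F, p and significance stars.  On a balanced design the decomposition
    SS_total = SS_A + SS_B + SS_AB + SS_error is exact.
    """

    table: pd.DataFrame
    factor_a: str
    factor_b: str

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "treatment",
    factor_b: str = "timepoint_days",
) -> AnovaResult:
    """Balanced fixed-effects two-way ANOVA with interaction.

    Uses the cell-mean closed forms: with a and b factor levels, n
    observations per cell and grand mean m,

        SS_A  = b n sum_i (m_i. - m)^2
        SS_B  = a n sum_j (m_.j - m)^2
        SS_AB = n sum_ij (m_ij - m_i. - m_.j + m)^2
        SS_E  = sum_ijk (y_ijk - m_ij)^2

    Unbalanced designs are rejected (the closed forms no longer give an
    orthogonal decomposition); use a regression framework for those.
    All-equal data yields SS_total = 0 and undefined (NaN) F ratios.
    """
    df = data[[value, factor_a, factor_b]].dropna()
    cells = df.groupby([factor_a, factor_b], observed=True)[value]
    counts = cells.count()
    a_levels = df[factor_a].nunique()
    b_levels = df[factor_b].nunique()
    if a_levels < 2 or b_levels < 2:
        raise ValueError("each factor needs at least 2 levels")
    if len(counts) != a_levels * b_levels or counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: the closed-form two-way ANOVA requires equal "
            "cell counts for every factor combination"
        )
    n = int(counts.iloc[0])
    if n < 2:
        raise ValueError("need at least 2 observations per cell")

    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    mean_a = df.groupby(factor_a, observed=True)[value].mean()
    mean_b = df.groupby(factor_b, observed=True)[value].mean()
    mean_ab = cells.mean()

    ss_a = b_levels * n * float(((mean_a - grand) ** 2).sum())
    ss_b = a_levels * n * float(((mean_b - grand) ** 2).sum())
    inter = (
        mean_ab
        - mean_a.reindex(mean_ab.index.get_level_values(0)).to_numpy()
        - mean_b.reindex(mean_ab.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ab = n * float((inter**2).sum())
    cell_mean_per_row = df.groupby([factor_a, factor_b], observed=True)[value].transform("mean")
    ss_e = float(((y - cell_mean_per_row.to_numpy(dtype=float)) ** 2).sum())
    ss_t = float(((y - grand) ** 2).sum())

    df_a = a_levels - 1
    df_b = b_levels - 1
    df_ab = df_a * df_b
    df_e = a_levels * b_levels * (n - 1)

    rows = []
    ms_e = ss_e / df_e
    for effect, ss, dfree in (
        (factor_a, ss_a, df_a),
        (factor_b, ss_b, df_b),
        (f"{factor_a}:{factor_b}", ss_ab, df_ab),
    ):
        ms = ss / dfree
        if ms_e == 0:
            f_val, p = float("nan"), float("nan")
            stars = "undefined"
        else:
            f_val = ms / ms_e
            p = float(sps.f.sf(f_val, dfree, df_e))
            stars = significance_stars(p)
        rows.append(
            {
                "effect": effect,
                "ss": ss,
                "df": dfree,
                "ms": ms,
                "F": f_val,
                "p": p,
                "significance": stars,
            }
        )
    rows.append(
        {
            "effect": "residual",
            "ss": ss_e,
            "df": df_e,
            "ms": ms_e,
            "F": float("nan"),
            "p": float("nan"),
            "significance": "",
        }
    )
    rows.append(
        {
            "effect": "total",
            "ss": ss_t,
            "df": df_a + df_b + df_ab + df_e,
            "ms": float("nan"),
            "F": float("nan"),
            "p": float("nan"),
            "significance": "",
        }
    )
    return AnovaResult(table=pd.DataFrame(rows), factor_a=factor_a, factor_b=factor_b)


def summarize_gas_exchange(
    records: pd.DataFrame,
    variables: tuple[str, ...] = ("a_sat", "gs", "e", "ci", "wue"),
    control_treatment: str = "control",
) -> pd.DataFrame:
    """Group means/SD plus percent change vs control per variable.

    Adds a ``wue`` column (A_sat/E) if absent.  Returns a tidy frame with
    one row per (treatment, timepoint_days, variable).
    """
    df = records.copy()
    if "wue" in variables and "wue" not in df.columns:
        df["wue"] = compute_wue(df["a_sat"], df["e"])
    rows = []
    for (treatment, timepoint), sub in df.groupby(["treatment", "timepoint_days"]):
        for var in variables:
            vals = sub[var].to_numpy(dtype=float)
            rows.append(
                {
                    "treatment": treatment,
                    "timepoint_days": timepoint,
                    "variable": var,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                    "n": int(vals.size),
                }
            )
    out = pd.DataFrame(rows)
    # percent change vs the control group at the same timepoint
    pct = []
    for _, row in out.iterrows():
        ctrl = out[
            (out["treatment"] == control_treatment)
            & (out["timepoint_days"] == row["timepoint_days"])
            & (out["variable"] == row["variable"])
        ]
        if ctrl.empty or ctrl["mean"].iloc[0] == 0:
            pct.append(float("nan"))
        else:
            pct.append(percent_change(ctrl["mean"].iloc[0], row["mean"]))
    out["pct_change_vs_control"] = pct
    return out
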