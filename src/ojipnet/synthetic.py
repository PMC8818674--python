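"""Seeded synthetic-data generators with stored ground truth.

Every generator is a pure function of its spec plus seed, so reruns are
bit-identical and every downstream stage can be tested against known truth
without any instrument or mass-spectrometry download.

OJIP transients are built as a sum of three Hill-in-time sigmoids — one per
kinetic phase (O-J, J-I, I-P) — which is smooth, monotone and has closed
forms at every cardinal time:

    F(t) = Fo + (F_M - Fo) * sum_k w_k * t^h / (t^h + tau_k^h)

plus optional Gaussian-in-log10(t) band perturbations (to inject L- or
K-band signatures at a chosen centre time) and i.i.d. Gaussian noise.  The
analytic noiseless values at 50/100/300 us, 2/30 ms and at the grid end
(the attainable maximum of a monotone curve) are recorded as ground truth.

Proteome tables are log-normal abundance draws; condition-specific proteins
are zeroed on one side, common proteins get a true fold change drawn
log-uniformly from per-class ranges, and the differential (HAP/LAP)
proteins share latent block factors so their replicate fold profiles are
correlated to a controllable target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ojipnet.transients import FluorescenceTransient, TransientSet, log_grid
from ojipnet.proteome import AbundanceTable

# --------------------------------------------------------------------------
# OJIP transients
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BandPerturbation:
    """A Gaussian bump/dip in log10(time).

    ``amplitude`` is the peak height as a fraction of Fv = F_M - Fo;
    ``sign`` +1 adds a band (K-band-like), -1 subtracts (L-band-like dip);
    ``width_decades`` is the Gaussian sigma on the log10 axis.
    """

    center_us: float
    width_decades: float = 0.25
    amplitude: float = 0.05
    sign: int = 1


@dataclass(frozen=True)
class OjipSimSpec:
    """Specification of one synthetic OJIP transient.

    Defaults emulate a healthy dark-adapted leaf: Fo = 500, F_M = 2500
    (Fv/Fm = 0.8), phase half-times 0.6/10/80 ms and weights 0.5/0.3/0.2,
    which place V_J near 0.5 and V_I near 0.8.  The grid is log-uniform
    from 10 us to 1 s.
    """

    fo: float = 500.0
    fm: float = 2_500.0
    step_times_us: tuple[float, float, float] = (600.0, 10_000.0, 80_000.0)
    step_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    hill_exponent: float = 2.0
    band_perturbations: tuple[BandPerturbation, ...] = ()
    noise_sd: float = 0.0
    points_per_decade: int = 40
    t_start_us: float = 10.0
    t_end_us: float = 1_000_000.0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.step_weights), 1.0, rel_tol=1e-9):
            raise ValueError("step weights must sum to 1")
        if self.fm <= self.fo:
            raise ValueError("fm must exceed fo")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class OjipGroundTruth:
    """Analytic noiseless values the extraction stage should recover."""

    f50us: float
    f100us: float
    f300us: float
    f2ms: float
    f30ms: float
    fm: float  # noiseless maximum attained on the grid
    fm_asymptote: float
    vj: float
    vi: float


def analytic_f(spec: OjipSimSpec, t_us) -> np.ndarray:
    """Closed-form noiseless fluorescence at time(s) ``t_us``."""
    t = np.asarray(t_us, dtype=float)
    h = spec.hill_exponent
    rise = np.zeros_like(t)
    for w, tau in zip(spec.step_weights, spec.step_times_us):
        rise = rise + w * t**h / (t**h + tau**h)
    f = spec.fo + (spec.fm - spec.fo) * rise
    fv = spec.fm - spec.fo
    for band in spec.band_perturbations:
        z = (np.log10(t) - np.log10(band.center_us)) / band.width_decades
        f = f + band.sign * band.amplitude * fv * np.exp(-0.5 * z**2)
    return f


def _truth_from_spec(spec: OjipSimSpec) -> OjipGroundTruth:
    f50, f100, f300, f2ms, f30ms = (
        float(analytic_f(spec, t)) for t in (50.0, 100.0, 300.0, 2_000.0, 30_000.0)
    )
    grid = log_grid(spec.t_start_us, spec.t_end_us, spec.points_per_decade)
    noiseless = analytic_f(spec, grid)
    fm_grid = float(noiseless.max())
    fv = fm_grid - f50
    return OjipGroundTruth(
        f50us=f50,
        f100us=f100,
        f300us=f300,
        f2ms=f2ms,
        f30ms=f30ms,
        fm=fm_grid,
        fm_asymptote=spec.fm,
        vj=(f2ms - f50) / fv,
        vi=(f30ms - f50) / fv,
    )


def simulate_ojip_transient(
    spec: OjipSimSpec,
    seed: int = 0,
    sample_id: str = "sim",
    treatment: str = "control",
    timepoint_days: int = 0,
    replicate: int = 1,
) -> tuple[FluorescenceTransient, OjipGroundTruth]:
    """Simulate one transient on a log grid, with its analytic ground truth.

    Raises if a band perturbation drives the curve non-physical (F <= 0).
    """
    rng = np.random.default_rng(seed)
    grid = log_grid(spec.t_start_us, spec.t_end_us, spec.points_per_decade)
    f = analytic_f(spec, grid)
    if np.any(f <= 0):
        raise ValueError("perturbation makes fluorescence non-physical (F <= 0)")
    if spec.noise_sd > 0:
        f = f + rng.normal(0.0, spec.noise_sd, size=f.size)
        f = np.clip(f, 1e-9, None)
    tr = FluorescenceTransient(
        sample_id=sample_id,
        treatment=treatment,
        timepoint_days=timepoint_days,
        replicate=replicate,
        time_us=grid,
        f=f,
    )
    return tr, _truth_from_spec(spec)


def simulate_salt_experiment(
    control_spec: OjipSimSpec,
    treated_specs: Mapping[str, OjipSimSpec] | OjipSimSpec,
    n_replicates: int = 4,
    seed: int = 0,
    timepoint_days: int = 15,
) -> tuple[TransientSet, dict[str, OjipGroundTruth]]:
    """Simulate a control + treated transient experiment.

    Replicates within a group differ only by measurement noise; treatment
    effects are encoded entirely in the spec differences (e.g. a lower
    F_M, or an injected L-band dip for a severe-salt group).  Returns the
    transient set and the per-group analytic truth.
    """
    if isinstance(treated_specs, OjipSimSpec):
        treated_specs = {"treated": treated_specs}
    groups: dict[str, OjipSimSpec] = {"control": control_spec, **treated_specs}
    seeds = np.random.SeedSequence(seed).spawn(len(groups) * n_replicates)
    transients = []
    truths: dict[str, OjipGroundTruth] = {}
    k = 0
    for name, spec in groups.items():
        truths[name] = _truth_from_spec(spec)
        for rep in range(1, n_replicates + 1):
            child_seed = int(seeds[k].generate_state(1)[0] % (2**31))
            k += 1
            tr, _ = simulate_ojip_transient(
                spec,
                seed=child_seed,
                sample_id=f"{name}_d{timepoint_days}_r{rep}",
                treatment=name,
                timepoint_days=timepoint_days,
                replicate=rep,
            )
            transients.append(tr)
    return TransientSet(transients), truths


def paper_like_ojip_specs(noise_sd: float = 10.0) -> dict[str, OjipSimSpec]:
    """Preset control/moderate/severe salt specs.

    The moderate group (300 mM-like) loses ~10% of F_M and gains a positive
    K-band; the severe group (500 mM-like) loses ~25% of F_M, gains Fo
    (inactive reaction centres) and carries a negative L-band dip centred
    at 150 us.
    """
    control = OjipSimSpec(noise_sd=noise_sd)
    moderate = OjipSimSpec(
        fo=520.0,
        fm=2_250.0,
        noise_sd=noise_sd,
        band_perturbations=(
            BandPerturbation(center_us=300.0, width_decades=0.22, amplitude=0.03, sign=1),
        ),
    )
    severe = OjipSimSpec(
        fo=560.0,
        fm=1_875.0,
        noise_sd=noise_sd,
        band_perturbations=(
            BandPerturbation(center_us=150.0, width_decades=0.22, amplitude=0.04, sign=-1),
        ),
    )
    return {"control": control, "NaCl300": moderate, "NaCl500": severe}


# --------------------------------------------------------------------------
# Proteome tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteomeSimSpec:
    """Specification of a synthetic label-free abundance table.

    Class fractions default to the composition typical of a salt-stress
    root proteome comparison: most common proteins unchanged, with small
    high- and low-abundance differential fractions.  Fold-change ranges per
    class are sampled log-uniformly.  Differential proteins are organised
    into latent blocks whose replicate fold profiles are correlated to
    ``block_r`` (within block) and uncorrelated across blocks.
    """

    n_proteins: int = 200
    n_replicates: int = 3
    frac_control_specific: float = 0.05
    frac_treated_specific: float = 0.05
    frac_hap: float = 0.078
    frac_lap: float = 0.098
    hap_fc_range: tuple[float, float] = (2.0, 8.0)
    lap_fc_range: tuple[float, float] = (0.125, 0.5)
    unchanged_fc_range: tuple[float, float] = (0.8, 1.25)
    abundance_log_mean: float = math.log(10_000.0)
    abundance_log_sd: float = 1.0
    n_blocks: int = 2
    block_r: float = 0.999
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        fracs = (
            self.frac_control_specific,
            self.frac_treated_specific,
            self.frac_hap,
            self.frac_lap,
        )
        if any(f < 0 for f in fracs) or sum(fracs[:2]) >= 1:
            raise ValueError("infeasible class fractions")
        if not 0 < self.block_r < 1:
            raise ValueError("block_r must be in (0, 1)")


def simulate_proteome_table(
    spec: ProteomeSimSpec, seed: int = 0
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Simulate an abundance table with per-protein ground truth.

    Returns the table and a truth frame with columns protein_id, status,
    cls, true_fc, block (block is -1 for non-differential proteins).
    ``noise_sd`` is the standard deviation of multiplicative log-normal
    replicate noise on the fold profile.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_proteins
    n_ctrl_spec = int(round(spec.frac_control_specific * n))
    n_trt_spec = int(round(spec.frac_treated_specific * n))
    n_common = n - n_ctrl_spec - n_trt_spec
    n_hap = int(round(spec.frac_hap * n_common))
    n_lap = int(round(spec.frac_lap * n_common))
    n_unch = n_common - n_hap - n_lap
    if min(n_common, n_hap, n_lap, n_unch) < 0:
        raise ValueError("infeasible class fractions for this n_proteins")

    statuses = (
        ["control_specific"] * n_ctrl_spec
        + ["treated_specific"] * n_trt_spec
        + ["common"] * n_common
    )
    classes: list[str | None] = [None] * (n_ctrl_spec + n_trt_spec) + (
        ["HAP"] * n_hap + ["LAP"] * n_lap + ["unchanged"] * n_unch
    )

    def log_uniform(lo: float, hi: float, size: int) -> np.ndarray:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    true_fc = np.full(n, np.nan)
    i0 = n_ctrl_spec + n_trt_spec
    true_fc[i0 : i0 + n_hap] = log_uniform(*spec.hap_fc_range, n_hap)
    true_fc[i0 + n_hap : i0 + n_hap + n_lap] = log_uniform(*spec.lap_fc_range, n_lap)
    true_fc[i0 + n_hap + n_lap : n] = log_uniform(*spec.unchanged_fc_range, n_unch)

    # latent block assignment for the differential (HAP+LAP) proteins
    blocks = np.full(n, -1, dtype=int)
    diff_idx = np.arange(i0, i0 + n_hap + n_lap)
    if diff_idx.size and spec.n_blocks > 0:
        blocks[diff_idx] = np.arange(diff_idx.size) % spec.n_blocks
    block_z = rng.standard_normal((max(spec.n_blocks, 1), spec.n_replicates))
    # within-block profile correlation approx 1 / (1 + sigma_w^2)
    sigma_w = math.sqrt(1.0 / spec.block_r - 1.0)

    base = np.exp(
        rng.normal(spec.abundance_log_mean, spec.abundance_log_sd, size=n)
    )
    # replicate-level technical scatter follows the same noise dial, so a
    # noiseless spec yields exactly reproducible replicates
    control = base[:, None] * np.exp(
        rng.normal(0.0, spec.noise_sd, size=(n, spec.n_replicates))
    )
    treated = np.empty_like(control)

    profile_spread = 0.2  # log-scale spread the block factor imprints
    for i in range(n):
        if statuses[i] == "control_specific":
            treated[i] = 0.0
        elif statuses[i] == "treated_specific":
            treated[i] = control[i]
            control[i] = 0.0
        else:
            fc = true_fc[i]
            if blocks[i] >= 0:
                u = block_z[blocks[i]] + sigma_w * rng.standard_normal(
                    spec.n_replicates
                )
                u = u / math.sqrt(1.0 + sigma_w**2)
                fold = fc * np.exp(profile_spread * u)
                # pin the pre-noise mean fold to the true value
                fold = fold * (fc / fold.mean())
            else:
                fold = np.full(spec.n_replicates, fc)
            if spec.noise_sd > 0:
                fold = fold * np.exp(
                    rng.normal(0.0, spec.noise_sd, size=spec.n_replicates)
                )
            treated[i] = control[i] * fold

    ids = [f"P{i + 1:05d}" for i in range(n)]
    data = pd.DataFrame(
        {
            "protein_id": ids,
            "accession": [f"ACC{i + 1:05d}" for i in range(n)],
            "description": [f"synthetic protein {i + 1}" for i in range(n)],
            "functional_group": pd.NA,
        }
    )
    for r in range(spec.n_replicates):
        data[f"control_r{r + 1}"] = control[:, r]
    for r in range(spec.n_replicates):
        data[f"treated_r{r + 1}"] = treated[:, r]
    tbl = AbundanceTable(
        data,
        [f"control_r{r + 1}" for r in range(spec.n_replicates)],
        [f"treated_r{r + 1}" for r in range(spec.n_replicates)],
    )
    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "status": statuses,
            "cls": classes,
            "true_fc": true_fc,
            "block": blocks,
        }
    )
    return tbl, truth


# --------------------------------------------------------------------------
# Gas exchange
# --------------------------------------------------------------------------


def paper_like_gas_means() -> dict[tuple[str, int], dict[str, float]]:
    """Preset group means emulating a severe salt response.

    The severe (500 mM-like) group carries a ~45% decline in A_sat together
    with proportionally stronger stomatal closure; the moderate group a
    ~25% decline.
    """
    out: dict[tuple[str, int], dict[str, float]] = {}
    for day in (15, 30):
        out[("control", day)] = {"a_sat": 20.0, "gs": 0.50, "e": 5.0, "ci": 280.0}
        out[("NaCl300", day)] = {"a_sat": 15.0, "gs": 0.33, "e": 4.0, "ci": 260.0}
        out[("NaCl500", day)] = {"a_sat": 11.0, "gs": 0.20, "e": 3.2, "ci": 240.0}
    return out


def simulate_gas_exchange(
    group_means: Mapping[tuple[str, int], Mapping[str, float]],
    sd: float | Mapping[str, float] = 0.0,
    n: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-plant gas-exchange records around group means.

    ``sd`` is either one absolute standard deviation for every variable or
    a per-variable mapping.  Values are clipped at zero (rates cannot be
    negative).  Returns a tidy frame with one row per plant.
    """
    rng = np.random.default_rng(seed)
    rows = []
    plant = 0
    for (treatment, timepoint), means in group_means.items():
        for rep in range(1, n + 1):
            plant += 1
            row = {
                "plant_id": f"plant{plant:03d}",
                "treatment": treatment,
                "timepoint_days": timepoint,
                "replicate": rep,
            }
            for var, mu in means.items():
                s = sd.get(var, 0.0) if isinstance(sd, Mapping) else sd
                val = mu if s == 0 else rng.normal(mu, s)
                row[var] = max(float(val), 0.0)
            rows.append(row)
    return pd.DataFrame(rows)
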