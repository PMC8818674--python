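"""End-to-end orchestration: configuration, staged execution, reporting.

``run_pipeline`` chains the analysis arms — JIP-test, difference bands,
gas-exchange statistics, proteome classification, correlation network —
over either provided input files or the packaged synthetic presets, writes
every stage's outputs under one directory, and finishes with a manifest and
a consolidated JSON summary.  All randomness flows from the single config
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ojipnet import bands as bands_mod
from ojipnet import gas as gas_mod
from ojipnet import jip as jip_mod
from ojipnet import proteome as prot_mod
from ojipnet import synthetic as sim_mod
from ojipnet.transients import TransientSet, read_transients, write_transients

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with field-standard defaults.

    Thresholds: fold-change class bounds 0.5/2.0 (the two-fold rule),
    correlation network |r| >= 0.99 with p <= 0.05, detection in >= 1
    replicate, difference-band grids at 60 points per decade, degree-class
    cuts at 40/50 edges.
    """

    seed: int = 0
    outdir: str = "ojipnet_out"
    transients_path: str | None = None
    abundance_path: str | None = None
    gas_path: str | None = None
    group_map_path: str | None = None
    control_treatment: str = "control"
    fc_low: float = 0.5
    fc_high: float = 2.0
    detection_min_reps: int = 1
    r_threshold: float = 0.99
    p_threshold: float = 0.05
    points_per_decade: int = 60
    degree_cuts: tuple[float, float] = (40.0, 50.0)
    n_replicates: int = 4
    sim_noise_sd: float = 10.0
    sim_proteome: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.degree_cuts, list):
            cfg.degree_cuts = tuple(cfg.degree_cuts)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["degree_cuts"] = list(self.degree_cuts)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _band_table(deltas: dict[str, dict[str, bands_mod.DeltaBand]]) -> pd.DataFrame:
    rows = []
    for treatment, by_kind in deltas.items():
        for kind, band in by_kind.items():
            for t, dv in zip(band.time_us, band.dv):
                rows.append(
                    {
                        "treatment": treatment,
                        "kind": kind,
                        "time_us": t,
                        "dv": dv,
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.outdir``.

    Returns the consolidated summary dict.  Stage failures raise
    :class:`StageError`; outputs written before the failure are retained and
    listed in ``manifest.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict[str, Any] = {"seed": config.seed}

    def _write_manifest(status: str) -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump({"status": status, "outputs": manifest}, fh, indent=2)

    def _track(path: Path) -> Path:
        manifest.append(str(path.relative_to(out)))
        return path

    try:
        stage = "transients"
        if config.transients_path:
            ts = read_transients(config.transients_path)
        else:
            specs = sim_mod.paper_like_ojip_specs(noise_sd=config.sim_noise_sd)
            control = specs.pop("control")
            sets = []
            for i, day in enumerate((15, 30)):
                s, _ = sim_mod.simulate_salt_experiment(
                    control,
                    specs,
                    n_replicates=config.n_replicates,
                    seed=config.seed + i,
                    timepoint_days=day,
                )
                sets.extend(s.transients)
            ts = TransientSet(sets)
        write_transients(ts, _track(out / "transients.csv"))
        summary["n_transients"] = len(ts)

        stage = "jip"
        jip_summary = jip_mod.summarize_group(ts)
        jip_summary.to_csv(_track(out / "jip_summary.csv"), index=False)
        ratios = jip_mod.ratio_table(jip_summary, config.control_treatment)
        ratios.to_csv(_track(out / "jip_ratios.csv"), index=False)
        flux = jip_mod.pipeline_flux_table(jip_summary, config.control_treatment)
        flux.to_csv(_track(out / "flux_table.csv"), index=False)
        fvfm = jip_summary.query("parameter == 'fv_fm'")
        summary["fv_fm_by_group"] = {
            f"{r.treatment}_d{r.timepoint_days}": r["mean"]
            for _, r in fvfm.iterrows()
        }

        stage = "bands"
        groups = ts.groups()
        deltas: dict[str, dict[str, bands_mod.DeltaBand]] = {}
        mm_fits: dict[str, dict] = {}
        for (treatment, day), members in groups.items():
            key = f"{treatment}_d{day}"
            ctrl_members = groups.get((config.control_treatment, day))
            if ctrl_members is None:
                continue
            vip_mean = bands_mod.mean_curve(
                [
                    bands_mod.relative_variable_fluorescence(
                        tr, "V_IP", config.points_per_decade
                    )
                    for tr in members
                ]
            )
            fit = bands_mod.fit_vip_mm(vip_mean)
            mm_fits[key] = {
                "km_ms": fit.km_ms,
                "vmax": fit.vmax,
                "rss": fit.rss,
                "converged": fit.converged,
            }
            if treatment == config.control_treatment:
                continue
            deltas[key] = {}
            for kind in ("V_OK", "V_OJ", "V_OI", "V_IP"):
                t_mean = bands_mod.mean_curve(
                    [
                        bands_mod.relative_variable_fluorescence(
                            tr, kind, config.points_per_decade
                        )
                        for tr in members
                    ]
                )
                c_mean = bands_mod.mean_curve(
                    [
                        bands_mod.relative_variable_fluorescence(
                            tr, kind, config.points_per_decade
                        )
                        for tr in ctrl_members
                    ]
                )
                deltas[key][kind] = bands_mod.delta_band(t_mean, c_mean)
        _band_table(deltas).to_csv(_track(out / "delta_bands.csv"), index=False)
        with open(_track(out / "mm_fits.json"), "w") as fh:
            json.dump(_jsonify(mm_fits), fh, indent=2)
        summary["band_peaks"] = {
            key: {
                kind: {"peak_time_us": b.peak_time_us, "peak_value": b.peak_value}
                for kind, b in by_kind.items()
            }
            for key, by_kind in deltas.items()
        }
        summary["mm_km_ms"] = {k: v["km_ms"] for k, v in mm_fits.items()}

        stage = "gas"
        if config.gas_path:
            gas_df = pd.read_csv(config.gas_path)
        else:
            gas_df = sim_mod.simulate_gas_exchange(
                sim_mod.paper_like_gas_means(),
                sd={"a_sat": 1.0, "gs": 0.03, "e": 0.3, "ci": 10.0},
                n=config.n_replicates,
                seed=config.seed + 100,
            )
        gas_df.to_csv(_track(out / "gas_records.csv"), index=False)
        gas_summary = gas_mod.summarize_gas_exchange(
            gas_df, control_treatment=config.control_treatment
        )
        gas_summary.to_csv(_track(out / "gas_summary.csv"), index=False)
        anova = gas_mod.two_way_anova(
            gas_df.rename(columns={"a_sat": "value"}),
            value="value",
            factor_a="treatment",
            factor_b="timepoint_days",
        )
        anova.table.to_csv(_track(out / "anova_a_sat.csv"), index=False)
        a_pct = gas_summary.query("variable == 'a_sat'")
        summary["a_sat_pct_change"] = {
            f"{r.treatment}_d{r.timepoint_days}": r["pct_change_vs_control"]
            for _, r in a_pct.iterrows()
        }

        stage = "proteome"
        if config.abundance_path:
            tbl = prot_mod.read_abundance_table(config.abundance_path)
        else:
            sim_spec = sim_mod.ProteomeSimSpec(**config.sim_proteome)
            tbl, _ = sim_mod.simulate_proteome_table(
                sim_spec, seed=config.seed + 200
            )
        prot_mod.write_abundance_table(tbl, _track(out / "abundance.csv"))
        cls = prot_mod.classify_fold_change(
            tbl,
            low=config.fc_low,
            high=config.fc_high,
            detection_min_reps=config.detection_min_reps,
        )
        cls.table.to_csv(_track(out / "fold_change_classes.csv"), index=False)
        group_map = (
            prot_mod.read_group_map(config.group_map_path)
            if config.group_map_path
            else {}
        )
        class_summary, group_summary = prot_mod.summarize_categories(cls, group_map)
        class_summary.to_csv(_track(out / "class_summary.csv"), index=False)
        group_summary.to_csv(_track(out / "group_summary.csv"), index=False)
        summary["class_counts"] = dict(
            zip(class_summary["cls"], class_summary["count"].astype(int))
        )

        stage = "network"
        differential = cls.proteins_in_class(prot_mod.CLASS_HAP) + cls.proteins_in_class(
            prot_mod.CLASS_LAP
        )
        if len(differential) >= 3:
            r_m, p_m = prot_mod.protein_correlation_matrix(tbl, differential)
            g = prot_mod.build_correlation_network(
                r_m, p_m, config.r_threshold, config.p_threshold
            )
            stats = prot_mod.graph_statistics(g)
            prot_mod.degree_classes(g, config.degree_cuts)
            prot_mod.export_graph(g, _track(out / "network.graphml"))
            prot_mod.export_graph(g, _track(out / "network.edges.tsv"), format="tsv")
            manifest.append("network.edges.tsv.nodes.tsv")
            summary["network"] = {
                k: v for k, v in stats.items() if k != "closeness"
            }
        else:
            summary["network"] = {"n_nodes": 0, "n_edges": 0, "skipped": True}

        stage = "report"
        with open(_track(out / "summary.json"), "w") as fh:
            json.dump(_jsonify(summary), fh, indent=2)
        _write_manifest("complete")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        _write_manifest(f"failed at {stage}")
        raise StageError(stage, exc) from exc
    return summary
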