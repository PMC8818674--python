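"""Data model, I/O and log-time resampling for fast fluorescence transients.

A transient is one leaf's polyphasic fluorescence rise recorded under
saturating light, sampled on an (approximately) logarithmic time grid from
tens of microseconds up to about a second.  The canonical internal time unit
is the microsecond; readers convert declared source units on ingest.

Interpolation between samples is linear in log10(time), because the OJIP
rise is log-time native: its inflections (O ~50 us, K ~300 us, J ~2 ms,
I ~30 ms, P = peak) are evenly spread on a log axis, not a linear one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: multiplicative factors to microseconds for declared source units
_UNIT_TO_US = {"us": 1.0, "ms": 1_000.0, "s": 1_000_000.0}

#: minimum coverage (us) needed for all cardinal points to be interpolable
FULL_RANGE_US = (50.0, 300_000.0)


class TransientFormatError(ValueError):
    """Raised when a transient file does not match the expected layout."""


class TransientValidationError(ValueError):
    """Raised when a transient violates a structural invariant."""


class ExtrapolationError(ValueError):
    """Raised when a time query falls outside the sampled range."""


@dataclass(frozen=True)
class FluorescenceTransient:
    """One leaf's (time, F) series with treatment/replicate metadata.

    ``time_us`` must be strictly increasing and ``f`` finite and positive
    (fluorescence is an intensity).  Downstream analyses additionally require
    coverage of [50 us, 300 ms]; see :meth:`covers_full_range`.
    """

    sample_id: str
    treatment: str
    timepoint_days: int
    replicate: int
    time_us: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_us, dtype=float)
        y = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "time_us", t)
        object.__setattr__(self, "f", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise TransientValidationError(
                f"{self.sample_id}: time and fluorescence must be 1-D and equal length"
            )
        if t.size < 2:
            raise TransientValidationError(f"{self.sample_id}: need at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise TransientValidationError(
                f"{self.sample_id}: time axis is not strictly increasing"
            )
        if t[0] <= 0:
            raise TransientValidationError(f"{self.sample_id}: times must be positive")
        if not np.all(np.isfinite(y)) or np.any(y <= 0):
            raise TransientValidationError(
                f"{self.sample_id}: fluorescence values must be finite and > 0"
            )

    def __len__(self) -> int:
        return int(self.time_us.size)

    def covers(self, t_start_us: float, t_end_us: float) -> bool:
        return self.time_us[0] <= t_start_us and self.time_us[-1] >= t_end_us

    def covers_full_range(self) -> bool:
        """Whether all JIP-test cardinal points are interpolable."""
        return len(self) >= 10 and self.covers(*FULL_RANGE_US)

    @property
    def group(self) -> tuple[str, int]:
        return (self.treatment, self.timepoint_days)


@dataclass
class TransientSet:
    """A collection of transients with unique sample ids.

    Grouping key is (treatment, timepoint_days); every group is non-empty by
    construction.
    """

    transients: list[FluorescenceTransient] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [tr.sample_id for tr in self.transients]
        dup = {s for s in ids if ids.count(s) > 1}
        if dup:
            raise TransientValidationError(f"duplicate sample ids: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.transients)

    def __iter__(self):
        return iter(self.transients)

    def groups(self) -> dict[tuple[str, int], list[FluorescenceTransient]]:
        out: dict[tuple[str, int], list[FluorescenceTransient]] = {}
        for tr in self.transients:
            out.setdefault(tr.group, []).append(tr)
        return out


def value_at(tr: FluorescenceTransient, t_us: float) -> float:
    """Fluorescence at ``t_us`` by linear interpolation in log10(time).

    Exact sample values are returned at grid points.  Queries outside the
    sampled range raise :class:`ExtrapolationError`.
    """
    t = float(t_us)
    if t < tr.time_us[0] or t > tr.time_us[-1]:
        raise ExtrapolationError(
            f"{tr.sample_id}: t={t} us outside sampled range "
            f"[{tr.time_us[0]}, {tr.time_us[-1]}] us"
        )
    return float(np.interp(np.log10(t), np.log10(tr.time_us), tr.f))


def values_at(tr: FluorescenceTransient, t_us: np.ndarray) -> np.ndarray:
    """Vectorized :func:`value_at`."""
    t = np.asarray(t_us, dtype=float)
    if t.min() < tr.time_us[0] or t.max() > tr.time_us[-1]:
        raise ExtrapolationError(
            f"{tr.sample_id}: query outside sampled range"
        )
    return np.interp(np.log10(t), np.log10(tr.time_us), tr.f)


def log_grid(t_start_us: float, t_end_us: float, points_per_decade: int) -> np.ndarray:
    """Uniform log10-time grid covering [t_start, t_end], endpoints exact."""
    lo, hi = np.log10(t_start_us), np.log10(t_end_us)
    n = max(int(np.ceil((hi - lo) * points_per_decade)) + 1, 2)
    grid = np.logspace(lo, hi, n)
    grid[0], grid[-1] = t_start_us, t_end_us
    return grid


def resample_log_grid(
    tr: FluorescenceTransient, points_per_decade: int
) -> FluorescenceTransient:
    """Resample onto a uniform log10-time grid spanning the original range.

    Endpoints are preserved exactly; interior values come from
    :func:`value_at`.
    """
    if points_per_decade < 4:
        raise ValueError("points_per_decade must be >= 4")
    grid = log_grid(tr.time_us[0], tr.time_us[-1], points_per_decade)
    vals = values_at(tr, grid)
    vals[0], vals[-1] = tr.f[0], tr.f[-1]
    return replace(tr, time_us=grid, f=vals)


def moving_median(tr: FluorescenceTransient, width: int = 5) -> FluorescenceTransient:
    """Optional odd-width moving-median denoiser (off by default everywhere).

    Edges use shrinking windows so the output length equals the input length.
    """
    if width % 2 == 0 or width < 3:
        raise ValueError("width must be odd and >= 3")
    half = width // 2
    out = np.empty_like(tr.f)
    for i in range(len(tr)):
        lo, hi = max(0, i - half), min(len(tr), i + half + 1)
        out[i] = np.median(tr.f[lo:hi])
    return replace(tr, f=out)


_LONG_COLUMNS = ["sample_id", "treatment", "timepoint_days", "replicate", "time_us", "f"]


def write_transients(ts: TransientSet, path: str | Path) -> Path:
    """Write a transient set as a long-format CSV.

    Columns: sample_id, treatment, timepoint_days, replicate, time_us, f.
    An empty set produces a header-only file.
    """
    path = Path(path)
    frames = []
    for tr in ts:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": tr.sample_id,
                    "treatment": tr.treatment,
                    "timepoint_days": tr.timepoint_days,
                    "replicate": tr.replicate,
                    "time_us": tr.time_us,
                    "f": tr.f,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=_LONG_COLUMNS
    )
    df.to_csv(path, index=False)
    return path


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".meta.yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def read_transients(
    path: str | Path,
    layout: str = "long",
    time_unit: str | None = None,
    time_column: str | None = None,
    metadata: Mapping[str, Mapping] | str | Path | None = None,
    require_full_range: bool = True,
) -> TransientSet:
    """Read transients from a long- or wide-layout CSV/TSV file.

    Long layout expects the columns written by :func:`write_transients`.
    Wide layout expects one time column plus one column per sample; sample
    metadata (treatment, timepoint_days, replicate) then comes from
    ``metadata`` (a mapping or a YAML file path), from a ``<stem>.meta.yaml``
    sidecar, or defaults to (sample_id, 0, 1).

    ``time_unit`` declares the source unit ('us', 'ms' or 's'); it may also
    be set by the sidecar key ``time_unit``.  Internally everything is us.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # round_trip parsing keeps write->read bit-identical
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")

    sidecar = _read_sidecar(path)
    if time_unit is None:
        time_unit = sidecar.get("time_unit", "us")
    if time_unit not in _UNIT_TO_US:
        raise TransientFormatError(f"unknown time unit {time_unit!r}")
    scale = _UNIT_TO_US[time_unit]

    if isinstance(metadata, (str, Path)):
        with open(metadata) as fh:
            metadata = yaml.safe_load(fh) or {}
    if metadata is None:
        metadata = sidecar.get("samples", {})

    transients: list[FluorescenceTransient] = []
    if layout == "long":
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise TransientFormatError(f"missing columns: {missing}")
        for sid, sub in df.groupby("sample_id", sort=False):
            t = sub["time_us"].to_numpy(dtype=float) * scale
            try:
                transients.append(
                    FluorescenceTransient(
                        sample_id=str(sid),
                        treatment=str(sub["treatment"].iloc[0]),
                        timepoint_days=int(sub["timepoint_days"].iloc[0]),
                        replicate=int(sub["replicate"].iloc[0]),
                        time_us=t,
                        f=sub["f"].to_numpy(dtype=float),
                    )
                )
            except TransientValidationError:
                raise
    elif layout == "wide":
        tc = time_column
        if tc is None:
            candidates = [c for c in df.columns if c.lower().startswith("time")]
            if not candidates:
                raise TransientFormatError("no time column found (expected 'time*')")
            tc = candidates[0]
        elif tc not in df.columns:
            raise TransientFormatError(f"missing time column {tc!r}")
        t = df[tc].to_numpy(dtype=float) * scale
        for col in df.columns:
            if col == tc:
                continue
            meta = dict(metadata.get(col, {}))
            transients.append(
                FluorescenceTransient(
                    sample_id=col,
                    treatment=str(meta.get("treatment", col)),
                    timepoint_days=int(meta.get("timepoint_days", 0)),
                    replicate=int(meta.get("replicate", 1)),
                    time_us=t,
                    f=df[col].to_numpy(dtype=float),
                )
            )
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if require_full_range:
        bad = [tr.sample_id for tr in transients if not tr.covers_full_range()]
        if bad:
            raise TransientValidationError(
                f"transients not covering [50 us, 300 ms] with >= 10 points: {bad}"
            )
    logger.info("read %d transients from %s", len(transients), path)
    return TransientSet(transients)
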