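import numpy as np
import pandas as pd
import pytest

from ojipnet.jip import CardinalPoints
from ojipnet.proteome import AbundanceTable
from ojipnet.transients import FluorescenceTransient


def make_transient(time_us, f, sample_id="t1", treatment="control", day=15, rep=1):
    return FluorescenceTransient(
        sample_id=sample_id,
        treatment=treatment,
        timepoint_days=day,
        replicate=rep,
        time_us=np.asarray(time_us, dtype=float),
        f=np.asarray(f, dtype=float),
    )


@pytest.fixture
def worked_cardinal_points():
    """Hand-checked landmark set: Fv/Fm=0.8, Vj=0.5, Vi=0.85, Mo=0.4/ms, Sm=20."""
    return CardinalPoints(
        fo=500.0,
        f100us=600.0,
        f300us=700.0,
        f2ms=1500.0,
        f30ms=2200.0,
        fm=2500.0,
        tfm_us=300_000.0,
        area_ms=20.0 * 2000.0,  # Sm = area / Fv = 20
    )


@pytest.fixture
def small_abundance_table():
    """5-protein table: one control-specific, one treated-specific, three common."""
    n = 3
    data = pd.DataFrame(
        {
            "protein_id": [f"P{i}" for i in range(1, 6)],
            "accession": [f"A{i}" for i in range(1, 6)],
            "description": ["p"] * 5,
            "functional_group": pd.NA,
            "control_r1": [10.0, 0.0, 100.0, 50.0, 40.0],
            "control_r2": [12.0, 0.0, 110.0, 50.0, 40.0],
            "control_r3": [11.0, 0.0, 90.0, 50.0, 40.0],
            "treated_r1": [0.0, 20.0, 100.0, 150.0, 10.0],
            "treated_r2": [0.0, 22.0, 105.0, 150.0, 10.0],
            "treated_r3": [0.0, 18.0, 95.0, 150.0, 10.0],
        }
    )
    return AbundanceTable(
        data,
        ["control_r1", "control_r2", "control_r3"],
        ["treated_r1", "treated_r2", "treated_r3"],
    )


def random_cardinal_points(rng):
    """A random valid, monotone cardinal-point draw."""
    fo = rng.uniform(200, 1000)
    fm = fo * rng.uniform(2.0, 6.0)
    fv = fm - fo
    # ordered interior steps keep vj, vi strictly inside (0, 1)
    q = np.sort(rng.uniform(0.05, 0.95, size=3))
    f300, f2ms, f30ms = fo + q * fv
    f100 = fo + rng.uniform(0.2, 0.8) * (f300 - fo)
    return CardinalPoints(
        fo=fo,
        f100us=f100,
        f300us=f300,
        f2ms=f2ms,
        f30ms=f30ms,
        fm=fm,
        tfm_us=rng.uniform(100_000, 900_000),
        area_ms=rng.uniform(0.1, 50.0) * fv,
    )
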