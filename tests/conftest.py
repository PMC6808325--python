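import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dialysis_cea import PatientRecord, default_parameters
from dialysis_cea.parameters import (
    CostProfile,
    EconomicSettings,
    ModelParameters,
    ParamRange,
    ScenarioSpec,
    TransitionRateSet,
    UtilitySet,
)


@pytest.fixture(scope="session")
def params():
    """The bundled published inputs (session-scoped; treat as read-only)."""
    return default_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_record(
    pid="p0",
    modality="HD",
    months=12.0,
    event="death",
    start=dt.date(2012, 1, 1),
    **kwargs,
):
    """A registry record with follow-up given in months."""
    end = start + dt.timedelta(days=round(months * 365.25 / 12))
    return PatientRecord(pid, modality, start, event, end, **kwargs)


def make_params(
    u_hd=0.854,
    u_capd=0.905,
    cost_hd=39790.58,
    cost_capd=37576.03,
    discount_rate=0.03,
    n_cycles=5,
    scenarios=None,
):
    """A minimal valid parameter bundle with arbitrary payoffs.

    The whole annual cost is carried by a single component so totals stay
    consistent whatever value is chosen.
    """

    def profile(modality, cost):
        zero = ParamRange(0.0, 0.0, 0.0)
        comps = {
            name: zero
            for name in (
                "outpatient",
                "access_surgeries",
                "building_land",
                "equipment",
                "staff",
                "overheads",
                "hospitalization",
            )
        }
        comps["dialysis_consumables"] = ParamRange(cost, 0.0, 2 * cost + 1.0)
        return CostProfile(modality, comps, ParamRange(cost, 0.0, 2 * cost + 1.0))

    scen = scenarios or {
        "base_case": ScenarioSpec("base_case", 0.6, 0.4),
        "scenario2": ScenarioSpec("scenario2", 0.5, 0.5),
    }
    return ModelParameters(
        costs={"HD": profile("HD", cost_hd), "CAPD": profile("CAPD", cost_capd)},
        utilities=UtilitySet(
            HD=ParamRange(u_hd, 0.0, 1.0), CAPD=ParamRange(u_capd, 0.0, 1.0)
        ),
        rates=TransitionRateSet(
            CAPD_HD=ParamRange(0.067, 0.058, 0.081),
            CAPD_death=ParamRange(0.134, 0.105, 0.151),
            HD_CAPD=ParamRange(0.007, 0.002, 0.011),
            HD_death=ParamRange(0.125, 0.119, 0.136),
        ),
        scenarios=scen,
        economics=EconomicSettings(discount_rate=discount_rate, n_cycles=n_cycles),
    )


def random_tpm(rng):
    """A random valid 3-state transition matrix with absorbing death."""
    m = np.eye(3)
    for row in (0, 1):
        exits = rng.uniform(0.0, 0.5, size=2)
        m[row] = 0.0
        m[row, row] = 1.0 - exits.sum()
        others = [c for c in range(3) if c != row]
        m[row, others[0]] = exits[0]
        m[row, others[1]] = exits[1]
    return m
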