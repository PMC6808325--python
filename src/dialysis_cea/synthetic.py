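"""Synthetic registry-style datasets for testing the estimation pipeline.

The published survival inputs come from a national dialysis registry that
is not publicly deposited, so this module generates patient-level records
with the statistical structure the analysis assumes: constant
(exponential) hazards of death and of modality switching that depend on
the *current* modality, competing exponential censoring causes (deceased-
donor transplant, recovered renal function, loss to follow-up), uniform
enrolment over a multi-year window, and administrative censoring at the
end of follow-up.  On a switch the modality changes and, by memorylessness,
all clocks restart under the new modality's hazards.

Default hazards are the published annual rates (death 0.125/y on HD,
0.134/y on CAPD; switching 0.007/y HD->CAPD, 0.067/y CAPD->HD) over a
2011-2015 enrolment window followed up to the end of 2016.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .markov import MarkovResult, TransitionMatrix, build_transition_matrix, run_cohort
from .parameters import ModelParameters, ParamRange, default_parameters
from .survival import DAYS_PER_YEAR, PatientRecord, RateEstimate, registry_event_rates

__all__ = ["GeneratorConfig", "PipelineFixture", "generate_registry", "end_to_end_fixture"]

_OTHER = {"HD": "CAPD", "CAPD": "HD"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic registry.

    Hazards are events per patient-year.  ``censor_hazards`` covers the
    three informative-censoring causes; their defaults are small, matching
    a setting where deceased-donor transplantation is rare.
    """

    n_patients: int = 5000
    modality_split: Mapping[str, float] = field(
        default_factory=lambda: {"HD": 0.6, "CAPD": 0.4}
    )
    death_hazard: Mapping[str, float] = field(
        default_factory=lambda: {"HD": 0.125, "CAPD": 0.134}
    )
    switch_hazard: Mapping[str, float] = field(
        default_factory=lambda: {"HD": 0.007, "CAPD": 0.067}
    )
    censor_hazards: Mapping[str, float] = field(
        default_factory=lambda: {
            "transplant": 0.012,
            "recovery": 0.004,
            "lost_to_follow_up": 0.010,
        }
    )
    enrolment_start: dt.date = dt.date(2011, 1, 1)
    enrolment_end: dt.date = dt.date(2015, 12, 31)
    admin_censor_date: dt.date = dt.date(2016, 12, 31)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.modality_split.values()) - 1.0) > 1e-9:
            raise ValueError("modality_split must sum to 1")
        for name, table in (
            ("death_hazard", self.death_hazard),
            ("switch_hazard", self.switch_hazard),
            ("censor_hazards", self.censor_hazards),
        ):
            if any(h < 0 for h in table.values()):
                raise ValueError(f"{name} must be >= 0")
        if not (self.enrolment_start <= self.enrolment_end < self.admin_censor_date):
            raise ValueError("enrolment window must precede the admin censor date")


def _exp_draw(rng: np.random.Generator, hazard: float) -> float:
    """An exponential waiting time in years; infinite when the hazard is 0."""
    if hazard <= 0:
        return math.inf
    return float(rng.exponential(1.0 / hazard))


def generate_registry(config: GeneratorConfig) -> list[PatientRecord]:
    """Simulate one registry extract; reproducible under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    window_days = (config.enrolment_end - config.enrolment_start).days

    modalities = list(config.modality_split)
    probs = np.array([config.modality_split[m] for m in modalities])
    first = rng.choice(len(modalities), size=config.n_patients, p=probs)
    start_offsets = rng.integers(0, window_days + 1, size=config.n_patients)

    records: list[PatientRecord] = []
    for i in range(config.n_patients):
        modality = modalities[first[i]]
        first_modality = modality
        start = config.enrolment_start + dt.timedelta(days=int(start_offsets[i]))
        horizon = (config.admin_censor_date - start).days / DAYS_PER_YEAR

        t = 0.0
        switch_time: float | None = None
        terminal_event = "administrative_censor"
        while True:
            clocks = {
                "death": _exp_draw(rng, config.death_hazard[modality]),
                "switch": _exp_draw(rng, config.switch_hazard[modality]),
            }
            for cause, hazard in config.censor_hazards.items():
                clocks[cause] = _exp_draw(rng, hazard)
            cause = min(clocks, key=clocks.get)
            wait = clocks[cause]
            if t + wait >= horizon:
                t = horizon
                terminal_event = "administrative_censor"
                break
            t += wait
            if cause == "switch":
                if switch_time is None:
                    switch_time = t
                modality = _OTHER[modality]
                continue
            terminal_event = cause
            break

        terminal = start + dt.timedelta(days=round(t * DAYS_PER_YEAR))
        terminal = min(terminal, config.admin_censor_date)
        switch_date = None
        if switch_time is not None:
            switch_date = start + dt.timedelta(days=round(switch_time * DAYS_PER_YEAR))
            switch_date = min(switch_date, terminal)
        records.append(
            PatientRecord(
                patient_id=f"P{i:06d}",
                first_modality=first_modality,
                start_date=start,
                terminal_event=terminal_event,
                terminal_date=terminal,
                switch_date=switch_date,
                final_modality=modality if switch_time is not None else None,
            )
        )
    return records


@dataclass(frozen=True)
class PipelineFixture:
    """All intermediates of one generate -> estimate -> model chain."""

    records: list[PatientRecord]
    rates: dict[str, RateEstimate]
    probabilities: dict[str, float]
    tpm: TransitionMatrix
    result: MarkovResult


def end_to_end_fixture(
    config: GeneratorConfig,
    params: ModelParameters | None = None,
    *,
    scenario: str = "base_case",
    attribution: str = "current",
) -> PipelineFixture:
    """Chain the full pipeline on one synthetic registry.

    Generates records, estimates per-modality annual death and switch
    rates by the mid-year-population method, converts them to per-cycle
    probabilities, rebuilds the transition matrix from the *estimated*
    rates, and runs the cohort model with the given parameter bundle's
    costs/utilities (published defaults when ``params`` is omitted).
    """
    from dataclasses import replace

    from .survival import rate_to_probability

    if params is None:
        params = default_parameters()
    records = generate_registry(config)
    years = range(config.enrolment_start.year, config.admin_censor_date.year + 1)
    rates = registry_event_rates(records, list(years), attribution=attribution)

    def as_range(key: str) -> ParamRange:
        r = max(rates[key].rate, 1e-9)  # rates must be > 0 for the bundle
        return ParamRange(mean=r, low=r, high=r)

    est_rates = replace(
        params.rates,
        HD_death=as_range("HD_death"),
        CAPD_death=as_range("CAPD_death"),
        HD_CAPD=as_range("HD_CAPD"),
        CAPD_HD=as_range("CAPD_HD"),
    )
    est_params = replace(params, rates=est_rates)
    probabilities = {
        key: rate_to_probability(getattr(est_rates, key).mean,
                                 params.economics.cycle_length)
        for key in ("HD_death", "CAPD_death", "HD_CAPD", "CAPD_HD")
    }
    tpm = build_transition_matrix(est_rates, params.economics.cycle_length)
    _, result = run_cohort(est_params.scenario(scenario), tpm, est_params)
    return PipelineFixture(
        records=records,
        rates=rates,
        probabilities=probabilities,
        tpm=tpm,
        result=result,
    )
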