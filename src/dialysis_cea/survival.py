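"""Survival and event-rate estimation from registry-style patient records.

Implements the estimation stage of the analysis: Kaplan-Meier product-limit
survivor functions (intention-to-treat by first modality — a patient keeps
their first modality even after switching, and a death after a switch still
counts against the first modality), restricted-mean survival (the model's
"life years"), and annual event rates computed as events in a calendar year
divided by the estimated mid-year patient population, averaged over years.
Rates convert to per-cycle probabilities with ``p = 1 - exp(-r t)``.

Time is handled in months internally (matching the monthly reporting grid
of registry survival tables) and converted to years for life-year outputs.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from lifelines.utils import survival_table_from_events

__all__ = [
    "TERMINAL_EVENTS",
    "DEFAULT_CENSOR_EVENTS",
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "PatientRecord",
    "KMCurve",
    "RateEstimate",
    "km_estimate",
    "restricted_mean_survival",
    "annual_event_rate",
    "rate_to_probability",
    "registry_event_rates",
    "records_to_frame",
    "frame_to_records",
    "read_registry_csv",
    "write_registry_csv",
]

TERMINAL_EVENTS = (
    "death",
    "switch",
    "transplant",
    "recovery",
    "lost_to_follow_up",
    "administrative_censor",
)

#: Censoring causes of the published analysis: transplant, recovered renal
#: function, loss to follow-up, plus the administrative end of follow-up.
DEFAULT_CENSOR_EVENTS = frozenset(
    {"transplant", "recovery", "lost_to_follow_up", "administrative_censor", "switch"}
)

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0


@dataclass(frozen=True)
class PatientRecord:
    """One registry row.

    ``first_modality`` is the modality at dialysis initiation and is never
    changed by a later switch (intention-to-treat attribution).  The
    optional ``switch_date``/``final_modality`` fields allow event rates to
    be attributed to the modality *current* at the event instead.
    """

    patient_id: str
    first_modality: str
    start_date: dt.date
    terminal_event: str
    terminal_date: dt.date
    switch_date: dt.date | None = None
    final_modality: str | None = None

    def __post_init__(self) -> None:
        if self.terminal_date < self.start_date:
            raise ValueError(
                f"record {self.patient_id}: terminal_date precedes start_date"
            )
        if self.terminal_event not in TERMINAL_EVENTS:
            raise ValueError(
                f"record {self.patient_id}: unknown terminal event "
                f"{self.terminal_event!r}"
            )
        if self.switch_date is not None and not (
            self.start_date <= self.switch_date <= self.terminal_date
        ):
            raise ValueError(
                f"record {self.patient_id}: switch_date outside follow-up"
            )

    @property
    def followup_months(self) -> float:
        return (self.terminal_date - self.start_date).days / DAYS_PER_MONTH

    def modality_at(self, date: dt.date) -> str:
        """Modality current on ``date`` (reconstructed from the first switch)."""
        if self.switch_date is not None and date >= self.switch_date:
            return self.final_modality or (
                "CAPD" if self.first_modality == "HD" else "HD"
            )
        return self.first_modality


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate on a monthly time axis.

    Arrays are aligned: ``survival[i]`` is S(t) for t in
    ``[times[i], times[i+1])``; ``times[0] == 0`` with ``survival[0] == 1``.
    ``std_err`` holds Greenwood standard errors of S(t).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    std_err: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "survival", "at_risk", "std_err"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        if not all(len(getattr(self, a)) == n
                   for a in ("survival", "at_risk", "std_err")):
            raise ValueError("KMCurve arrays must have equal length")
        if n == 0 or self.times[0] != 0 or self.survival[0] != 1.0:
            raise ValueError("curve must start at (t=0, S=1)")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((self.survival < -1e-12) | (self.survival > 1 + 1e-12)):
            raise ValueError("survival values must lie in [0, 1]")

    def survival_at(self, t_months: float) -> float:
        """S(t), right-continuous step interpolation."""
        idx = int(np.searchsorted(self.times, t_months, side="right")) - 1
        return float(self.survival[max(idx, 0)])


@dataclass(frozen=True)
class RateEstimate:
    """An annual event rate: events over estimated mid-year population.

    ``per_year_breakdown`` rows are (year, events, midyear_population,
    rate); ``rate`` is the equal-weight mean of the per-year rates.
    """

    events: float
    midyear_population: float
    rate: float
    per_year_breakdown: tuple[tuple[int, float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")

    @property
    def std_err(self) -> float | None:
        """Poisson (delta-method) standard error of the mean annual rate."""
        if not self.per_year_breakdown:
            return None
        k = len(self.per_year_breakdown)
        var = sum(ev / (pop * pop) for _, ev, pop, _ in self.per_year_breakdown)
        return math.sqrt(var) / k


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_estimate(
    records: Sequence[PatientRecord],
    event_of_interest: Iterable[str] = ("death",),
    censor_events: Iterable[str] | None = None,
) -> KMCurve:
    """Product-limit survivor function S(t) = prod(1 - d_i / n_i).

    Attribution is intention-to-treat: each record contributes follow-up
    from dialysis initiation to its terminal date under its *first*
    modality, so filter ``records`` by ``first_modality`` for per-modality
    curves.  Ties between events and censorings at the same time are
    resolved events-first (the standard KM convention, and what the risk
    table from ``lifelines`` produces).
    """
    if len(records) == 0:
        raise ValueError("km_estimate requires at least one record")
    events = frozenset(event_of_interest)
    censors = (
        frozenset(censor_events)
        if censor_events is not None
        else frozenset(TERMINAL_EVENTS) - events
    )
    if events & censors:
        raise ValueError(f"event/censor sets overlap: {sorted(events & censors)}")
    seen = {r.terminal_event for r in records}
    uncovered = seen - events - censors
    if uncovered:
        raise ValueError(f"terminal events not classified: {sorted(uncovered)}")

    durations = np.array([r.followup_months for r in records])
    observed = np.array([r.terminal_event in events for r in records], dtype=bool)

    if not observed.any():
        warnings.warn("all records censored; survivor function is flat at 1")
        tmax = float(durations.max())
        times = np.array([0.0, tmax]) if tmax > 0 else np.array([0.0])
        n = len(records)
        return KMCurve(
            times=times,
            survival=np.ones_like(times),
            at_risk=np.full_like(times, n),
            std_err=np.zeros_like(times),
        )

    table = survival_table_from_events(durations, observed)
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    t = table.index.to_numpy(dtype=float)

    surv = np.cumprod(1.0 - d / n)
    # Greenwood: Var[S(t)] = S(t)^2 * sum d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    se = surv * np.sqrt(np.cumsum(terms))

    if t[0] != 0.0 or d[0] > 0:
        # ensure the curve starts at (0, 1); events dated exactly at t=0
        # drop S immediately after the origin (duplicated time 0)
        t = np.concatenate([[0.0], t])
        surv = np.concatenate([[1.0], surv])
        n = np.concatenate([[float(len(records))], n])
        se = np.concatenate([[0.0], se])
    return KMCurve(times=t, survival=surv, at_risk=n, std_err=se)


def restricted_mean_survival(curve: KMCurve, horizon: float) -> float:
    """Area under the KM step function from 0 to ``horizon`` years.

    If the horizon exceeds the last observed time, S is held at its last
    value (with a warning), which is the usual registry convention when
    follow-up is administratively truncated.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    horizon_m = horizon * 12.0
    times = curve.times
    surv = curve.survival
    if horizon_m > times[-1] + 1e-9 and surv[-1] > 0:
        warnings.warn(
            f"horizon {horizon} y exceeds last follow-up "
            f"({times[-1] / 12.0:.2f} y); holding S at {surv[-1]:.3f}"
        )
    edges = np.concatenate([times, [max(horizon_m, times[-1])]])
    widths = np.clip(np.minimum(edges[1:], horizon_m) - np.minimum(edges[:-1], horizon_m), 0, None)
    area_months = float(np.sum(widths * surv))
    return area_months / 12.0


# ---------------------------------------------------------------------------
# annual rates


def annual_event_rate(
    events: float | Sequence[float],
    midyear_population: float | Sequence[float],
    years: Sequence[int] | None = None,
) -> RateEstimate:
    """Events per patient-year from mid-year population counts.

    Scalar inputs give a single-year rate.  Sequence inputs give per-year
    rates averaged with equal weight across years (the convention for a
    mean annual rate over an observation window).
    """
    ev = np.atleast_1d(np.asarray(events, dtype=float))
    pop = np.atleast_1d(np.asarray(midyear_population, dtype=float))
    if ev.shape != pop.shape:
        raise ValueError("events and midyear_population must align")
    if np.any(pop <= 0):
        raise ValueError("midyear_population must be > 0")
    if np.any(ev < 0):
        raise ValueError("event counts must be >= 0")
    yearly = ev / pop
    breakdown = None
    if years is not None:
        breakdown = tuple(
            (int(y), float(e), float(p), float(r))
            for y, e, p, r in zip(years, ev, pop, yearly)
        )
    return RateEstimate(
        events=float(ev.sum()),
        midyear_population=float(pop.mean()),
        rate=float(yearly.mean()),
        per_year_breakdown=breakdown,
    )


def rate_to_probability(rate: float, t: float = 1.0) -> float:
    """Per-cycle probability from an annual rate: ``p = 1 - exp(-r t)``."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    return -math.expm1(-rate * t)


# ---------------------------------------------------------------------------
# registry-level rate estimation


def _on_dialysis(record: PatientRecord, date: dt.date) -> bool:
    # A patient administratively censored on the snapshot date is still on
    # dialysis that day (their follow-up, not their treatment, ended).
    if record.terminal_event == "administrative_censor":
        return record.start_date <= date <= record.terminal_date
    return record.start_date <= date < record.terminal_date


def registry_event_rates(
    records: Sequence[PatientRecord],
    years: Sequence[int],
    *,
    attribution: Literal["current", "first"] = "current",
) -> dict[str, RateEstimate]:
    """Per-modality annual death and switch rates from a registry extract.

    For each calendar year the mid-year population of a modality is the
    average of its on-dialysis counts on 1 January and 31 December
    (patients enrolled and not yet terminated), and events are deaths (or
    modality switches) dated within the year.  Deaths are attributed to the
    modality ``current`` at death (default) or to the ``first`` modality;
    switch events are always attributed to the modality being left.  Years
    whose mid-year population is zero are dropped from the average.

    Returns rates keyed ``HD_death``, ``CAPD_death``, ``HD_CAPD``,
    ``CAPD_HD``.
    """
    if attribution not in ("current", "first"):
        raise ValueError(f"unknown attribution {attribution!r}")

    def death_modality(r: PatientRecord) -> str:
        if attribution == "first":
            return r.first_modality
        return r.modality_at(r.terminal_date)

    counts: dict[str, dict[int, float]] = {
        k: {} for k in ("HD_death", "CAPD_death", "HD_CAPD", "CAPD_HD")
    }
    pops: dict[str, dict[int, float]] = {"HD": {}, "CAPD": {}}

    for year in years:
        jan1 = dt.date(year, 1, 1)
        dec31 = dt.date(year, 12, 31)
        pop = {"HD": [0, 0], "CAPD": [0, 0]}
        for r in records:
            for i, date in enumerate((jan1, dec31)):
                if _on_dialysis(r, date):
                    mod = r.modality_at(date) if attribution == "current" else r.first_modality
                    pop[mod][i] += 1
        for mod in ("HD", "CAPD"):
            pops[mod][year] = 0.5 * (pop[mod][0] + pop[mod][1])
        for key in counts:
            counts[key][year] = 0.0
        for r in records:
            if r.terminal_event == "death" and jan1 <= r.terminal_date <= dec31:
                counts[f"{death_modality(r)}_death"][year] += 1
            if r.switch_date is not None and jan1 <= r.switch_date <= dec31:
                origin = r.first_modality  # modality being left at first switch
                dest = "CAPD" if origin == "HD" else "HD"
                counts[f"{origin}_{dest}"][year] += 1

    out: dict[str, RateEstimate] = {}
    for key, per_year in counts.items():
        origin = key.split("_")[0]
        usable = [y for y in years if pops[origin][y] > 0]
        if not usable:
            raise ValueError(f"no population at risk for {origin} in any year")
        out[key] = annual_event_rate(
            [per_year[y] for y in usable],
            [pops[origin][y] for y in usable],
            years=usable,
        )
    return out


# ---------------------------------------------------------------------------
# registry I/O

_CSV_COLUMNS = (
    "patient_id",
    "first_modality",
    "start_date",
    "terminal_event",
    "terminal_date",
    "switch_date",
    "final_modality",
)


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "first_modality": r.first_modality,
            "start_date": r.start_date.isoformat(),
            "terminal_event": r.terminal_event,
            "terminal_date": r.terminal_date.isoformat(),
            "switch_date": r.switch_date.isoformat() if r.switch_date else "",
            "final_modality": r.final_modality or "",
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(_CSV_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    def parse_date(value) -> dt.date | None:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        text = str(value).strip()
        return dt.date.fromisoformat(text) if text else None

    records = []
    for row in frame.to_dict("records"):
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                first_modality=str(row["first_modality"]),
                start_date=parse_date(row["start_date"]),
                terminal_event=str(row["terminal_event"]),
                terminal_date=parse_date(row["terminal_date"]),
                switch_date=parse_date(row.get("switch_date")),
                final_modality=(str(row["final_modality"]).strip() or None)
                if row.get("final_modality") is not None
                else None,
            )
        )
    return records


def write_registry_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def read_registry_csv(path: str | Path) -> list[PatientRecord]:
    return frame_to_records(pd.read_csv(path, dtype=str, keep_default_na=False))
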