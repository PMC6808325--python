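"""Deterministic and probabilistic sensitivity analysis.

One-way analysis pins each uncertain input at its published low/high bound
(all others at their means), reruns the Markov model for the compared
provision strategies, and records the incremental net monetary benefit —
the tornado diagram's bars.  Probabilistic analysis (second-order Monte
Carlo) samples every cost component from a gamma distribution and every
utility and transition rate from a beta distribution, fitted by method of
moments with the published range treated as a central 95% interval
(SD = (high - low)/3.92; SD = range/4 available for a more conservative
spread), and summarizes strategy uncertainty as cost-effectiveness
acceptability curves (CEAC).

Parameter draws are shared across strategies within an iteration (common
random numbers), so strategy differences reflect the initial-mix decision
rather than sampling noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import net_monetary_benefit
from .markov import build_transition_matrix, run_cohort
from .parameters import (
    MODALITIES,
    RATE_KEYS,
    ModelParameters,
    ValidationError,
)

__all__ = [
    "DistributionSpec",
    "TornadoEntry",
    "PSAResult",
    "CEACCurve",
    "fit_distribution",
    "parameter_distributions",
    "one_way_tornado",
    "run_psa",
    "ceac",
    "default_threshold_grid",
]

#: z-width of a central 95% normal interval; the published (low, high)
#: ranges are interpreted as such an interval when fitting distributions.
Z95 = 3.92


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one uncertain input.

    ``params`` holds (shape, rate) for gamma and (alpha, beta) for beta.
    A zero-variance input degenerates to a point mass at the mean.
    """

    family: Literal["gamma", "beta", "degenerate"]
    mean: float
    low: float
    high: float
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "degenerate":
            return (
                self.mean if size is None else np.full(size, self.mean, dtype=float)
            )
        if self.family == "gamma":
            shape, rate = self.params
            return rng.gamma(shape, 1.0 / rate, size)
        alpha, beta = self.params
        return rng.beta(alpha, beta, size)


def fit_distribution(
    family: str, mean: float, low: float, high: float, *, z: float = Z95
) -> DistributionSpec:
    """Method-of-moments gamma/beta fit from a mean and a 95% range.

    SD is taken as ``(high - low) / z`` (z = 3.92 by default).  Gamma:
    shape = mean^2/var, rate = mean/var.  Beta: alpha = mean * nu,
    beta = (1 - mean) * nu with nu = mean(1-mean)/var - 1.  The fitted
    distribution's mean equals the input mean exactly.
    """
    if not (low <= mean <= high):
        raise ValidationError(f"mean {mean} outside range [{low}, {high}]")
    sd = (high - low) / z
    if sd == 0.0:
        return DistributionSpec("degenerate", mean, low, high, ())
    var = sd * sd

    if family == "gamma":
        if low < 0:
            raise ValidationError("gamma support requires low >= 0")
        if mean == 0.0:
            warnings.warn("gamma with zero mean degenerates to a point mass at 0")
            return DistributionSpec("degenerate", mean, low, high, ())
        shape = mean * mean / var
        rate = mean / var
        return DistributionSpec("gamma", mean, low, high, (shape, rate))

    if family == "beta":
        if not (0.0 <= low and high <= 1.0):
            raise ValidationError("beta support requires [low, high] within [0, 1]")
        if mean in (0.0, 1.0):
            return DistributionSpec("degenerate", mean, low, high, ())
        if var >= mean * (1.0 - mean):
            raise ValidationError(
                f"beta infeasible: variance {var:.4g} >= mean(1-mean) "
                f"{mean * (1 - mean):.4g}"
            )
        nu = mean * (1.0 - mean) / var - 1.0
        return DistributionSpec("beta", mean, low, high, (mean * nu, (1.0 - mean) * nu))

    raise ValidationError(f"unknown distribution family {family!r}")


def parameter_distributions(
    params: ModelParameters, *, z: float = Z95
) -> dict[str, DistributionSpec]:
    """Fitted sampling distribution for every labelled uncertain input.

    Costs are gamma; utilities and transition rates are beta (rates are
    well below 1 event/patient-year, so the unit-interval support is not
    binding).  Utility ranges reaching above 1 are clipped to 1 with a
    warning before fitting.
    """
    specs: dict[str, DistributionSpec] = {}
    for label, rng in params.labelled_inputs().items():
        if label.startswith("c"):
            specs[label] = fit_distribution("gamma", rng.mean, rng.low, rng.high, z=z)
        else:
            low, high = rng.low, rng.high
            if high > 1.0:
                warnings.warn(f"{label}: range top {high} clipped to 1.0")
                high = 1.0
            specs[label] = fit_distribution("beta", rng.mean, low, high, z=z)
    return specs


# ---------------------------------------------------------------------------
# one-way (tornado) analysis


@dataclass(frozen=True)
class TornadoEntry:
    """NMB excursion of one input across its published range."""

    label: str
    low: float
    high: float
    nmb_at_low: float
    nmb_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.nmb_at_high - self.nmb_at_low)


def _strategy_outcomes(
    params: ModelParameters,
    scenario: str,
    *,
    discounted: bool,
) -> tuple[float, float]:
    """(cost, qaly) per member of the initial cohort for one scenario."""
    tpm = build_transition_matrix(params.rates, params.economics.cycle_length)
    _, res = run_cohort(params.scenario(scenario), tpm, params)
    if discounted:
        return res.disc_cost, res.disc_qaly
    return res.total_cost, res.total_qaly


def incremental_nmb(
    params: ModelParameters,
    intervention: str,
    comparator: str,
    threshold: float,
    *,
    discounted: bool = True,
) -> float:
    """NMB of adopting ``intervention`` over ``comparator`` at a threshold."""
    ci, qi = _strategy_outcomes(params, intervention, discounted=discounted)
    cc, qc = _strategy_outcomes(params, comparator, discounted=discounted)
    return net_monetary_benefit(qi - qc, ci - cc, threshold)


def one_way_tornado(
    params: ModelParameters,
    *,
    intervention: str = "scenario2",
    comparator: str = "base_case",
    threshold: float | None = None,
    discounted: bool = True,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis of the incremental NMB.

    Each labelled input in turn is pinned at its low then high bound with
    all other inputs at their means; the Markov model is rerun for both
    strategies and the incremental NMB recorded.  Entries are returned
    sorted by descending bar width (ties broken by label), which is the
    tornado-diagram ordering.  The default comparison is the CAPD-expansion
    strategy (50:50 mix) against current practice (60:40).
    """
    if threshold is None:
        threshold = params.economics.wtp_thresholds["cost_effective"]
    entries = []
    for label, rng in sorted(params.labelled_inputs().items()):
        low, high = rng.low, rng.high
        if label.startswith("u") and high > 1.0:
            warnings.warn(f"{label}: range top {high} clipped to 1.0")
            high = 1.0
        nmb_low = incremental_nmb(
            params.with_value(label, low), intervention, comparator,
            threshold, discounted=discounted,
        )
        nmb_high = incremental_nmb(
            params.with_value(label, high), intervention, comparator,
            threshold, discounted=discounted,
        )
        entries.append(TornadoEntry(label, low, high, nmb_low, nmb_high))
    entries.sort(key=lambda e: (-e.bar_width, e.label))
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo sample of parameter draws and per-strategy outcomes.

    ``parameters`` is (n_iterations x labels); ``outcomes`` is long-form
    with one row per (iteration, scenario) and discounted/undiscounted
    cost and QALY columns.  ``n_rejected`` counts redraws forced by a draw
    whose exit probabilities would have summed to >= 1.
    """

    parameters: pd.DataFrame
    outcomes: pd.DataFrame
    n_iterations: int
    n_rejected: int
    seed: int | None

    def scenario_outcomes(
        self, scenario: str, *, discounted: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        sub = self.outcomes[self.outcomes["scenario"] == scenario]
        prefix = "disc_" if discounted else "undisc_"
        return (
            sub[prefix + "cost"].to_numpy(),
            sub[prefix + "qaly"].to_numpy(),
        )


def run_psa(
    params: ModelParameters,
    n_iterations: int = 1000,
    seed: int | None = None,
    *,
    scenarios: Sequence[str] | None = None,
    z: float = Z95,
    max_redraws: int = 1000,
) -> PSAResult:
    """Second-order Monte Carlo over all uncertain inputs.

    Per iteration every cost component, utility and transition rate is
    drawn from its fitted distribution, the transition matrix rebuilt, and
    every scenario run on the same draw.  Draws implying per-state exit
    probabilities >= 1 are rejected and redrawn (counted).  Fixing ``seed``
    makes the sample bit-reproducible.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    specs = parameter_distributions(params, z=z)
    labels = list(specs)
    scenario_names = list(scenarios) if scenarios is not None else list(params.scenarios)

    draws = np.empty((n_iterations, len(labels)))
    rows: list[dict] = []
    n_rejected = 0

    for it in range(n_iterations):
        for attempt in range(max_redraws + 1):
            draw = {lab: float(specs[lab].sample(rng)) for lab in labels}
            # feasibility of the implied transition matrix
            exits_ok = all(
                (1.0 - np.exp(-draw[f"p{a}_{b1}"])) + (1.0 - np.exp(-draw[f"p{a}_{b2}"]))
                < 1.0
                for a, b1, b2 in (("HD", "CAPD", "death"), ("CAPD", "HD", "death"))
            )
            if exits_ok:
                break
            n_rejected += 1
        else:
            raise ValidationError("could not draw a feasible transition matrix")

        draws[it] = [draw[lab] for lab in labels]
        sampled = params
        for lab, value in draw.items():
            sampled = _with_sampled_value(sampled, lab, value)
        tpm = build_transition_matrix(sampled.rates, sampled.economics.cycle_length)
        for name in scenario_names:
            _, res = run_cohort(sampled.scenario(name), tpm, sampled)
            rows.append(
                {
                    "iteration": it,
                    "scenario": name,
                    "disc_cost": res.disc_cost,
                    "disc_qaly": res.disc_qaly,
                    "undisc_cost": res.total_cost,
                    "undisc_qaly": res.total_qaly,
                }
            )

    return PSAResult(
        parameters=pd.DataFrame(draws, columns=labels),
        outcomes=pd.DataFrame(rows),
        n_iterations=n_iterations,
        n_rejected=n_rejected,
        seed=seed,
    )


def _with_sampled_value(
    params: ModelParameters, label: str, value: float
) -> ModelParameters:
    """Like ``ModelParameters.with_value`` but tolerant of out-of-range draws.

    Random draws legitimately fall outside the published (low, high) range
    (the range is a 95% interval, not the support), so the replacement
    widens the range to contain the draw before substituting.
    """
    from dataclasses import replace as _replace

    inputs = params.labelled_inputs()
    rng = inputs[label]
    if rng.low <= value <= rng.high:
        return params.with_value(label, value)
    widened = params
    # temporarily widen by rebuilding through with_value on a stretched range
    target = inputs[label]
    new_low = min(target.low, value)
    new_high = max(target.high, value)
    # reuse with_value by patching the range first
    stretched = _replace(target, low=new_low, high=new_high)
    widened = _patch_range(params, label, stretched)
    return widened.with_value(label, value)


def _patch_range(params: ModelParameters, label: str, new_range) -> ModelParameters:
    from dataclasses import replace as _replace

    if label in ("uHD", "uCAPD"):
        modality = label[1:]
        return _replace(
            params, utilities=_replace(params.utilities, **{modality: new_range})
        )
    if label.startswith("p") and label[1:] in RATE_KEYS:
        return _replace(
            params, rates=_replace(params.rates, **{label[1:]: new_range})
        )
    # cost component
    for modality in MODALITIES:
        profile = params.costs[modality]
        for comp in profile.components:
            from .parameters import _LABEL_SUFFIX

            if label == f"c{modality}_{_LABEL_SUFFIX[comp]}":
                comps = dict(profile.components)
                comps[comp] = new_range
                return _replace(
                    params,
                    costs={**params.costs, modality: _replace(profile, components=comps)},
                )
    raise ValidationError(f"unknown input label {label!r}")


# ---------------------------------------------------------------------------
# CEAC


@dataclass(frozen=True)
class CEACCurve:
    """Probability each strategy has the highest NMB, per WTP threshold."""

    thresholds: np.ndarray
    probabilities: pd.DataFrame  # index: threshold, columns: scenarios

    def probability(self, scenario: str, threshold: float) -> float:
        idx = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.probabilities.iloc[idx][scenario])


def default_threshold_grid() -> np.ndarray:
    """RM0 to RM200,000 in RM5,000 steps (covers both GDP thresholds)."""
    return np.arange(0.0, 200_001.0, 5_000.0)


def ceac(
    psa: PSAResult,
    thresholds: Sequence[float] | None = None,
    *,
    discounted: bool = True,
) -> CEACCurve:
    """Cost-effectiveness acceptability curves from a PSA sample.

    At each threshold the probability of a strategy is the fraction of
    iterations in which it attains the maximum NMB; exact ties share the
    iteration equally.  Probabilities across strategies sum to 1 at every
    threshold.
    """
    grid = (
        np.asarray(list(thresholds), dtype=float)
        if thresholds is not None
        else default_threshold_grid()
    )
    if grid.size == 0:
        raise ValidationError("threshold grid must be non-empty")
    scenario_names = list(dict.fromkeys(psa.outcomes["scenario"]))
    costs = np.column_stack(
        [psa.scenario_outcomes(s, discounted=discounted)[0] for s in scenario_names]
    )
    qalys = np.column_stack(
        [psa.scenario_outcomes(s, discounted=discounted)[1] for s in scenario_names]
    )

    probs = np.zeros((grid.size, len(scenario_names)))
    for gi, lam in enumerate(grid):
        nmb = qalys * lam - costs  # (n_iter, n_scen)
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        probs[gi] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)

    return CEACCurve(
        thresholds=grid,
        probabilities=pd.DataFrame(probs, index=grid, columns=scenario_names),
    )
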