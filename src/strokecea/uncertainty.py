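"""Deterministic and probabilistic sensitivity analysis.

Every model quantity with an uncertainty range enters as a
:class:`Parameter` (base value, lower, upper, distribution family).  For
probabilistic analysis the printed range is read as a 95 % interval, so
``SE = (upper - lower) / 3.92``, and the family's natural parameters follow
by method of moments:

* gamma: ``shape = (base/SE)^2``, ``scale = SE^2/base`` (costs, rates);
* beta: ``a + b = base(1-base)/SE^2 - 1``, ``a = base(a+b)`` (utilities);
* lognormal: ``meanlog = ln(base)``, ``sdlog = (ln upper - ln lower)/3.92``
  (hazard ratios);
* uniform on ``(lower, upper)`` (discount rates).

One-way DSA re-runs the full pipeline at each parameter's bounds and ranks
spreads for a tornado diagram; the 5,000-iteration PSA redraws every
non-fixed parameter per iteration and feeds the cost-effectiveness
acceptability curve, the probability that the sublingual arm is
cost-effective as a function of willingness-to-pay.  Scenario analysis
re-runs the base case over alternative horizons (90 days to 40 years) and
under the ATT estimand.

The weighted day-90 mRS distributions are treated as fixed pipeline inputs
and are not sampled (a Dirichlet option exists behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_model import (
    ModelSpec,
    MortalityHRs,
    PostRecurrenceDistribution,
    RecurrenceSchedule,
    run_decision_tree,
    run_markov,
    transition_matrices,
)
from .economics import (
    GDP_PER_CAPITA_2024,
    CEResult,
    CostSet,
    UtilitySet,
    accrue,
    accrue_tree_only,
    compare,
)
from .weighting import MRSDistribution

DISTRIBUTIONS = ("lognormal", "gamma", "beta", "uniform", "fixed")

TREE_ONLY_HORIZON = 0.25  # "90 days" scenario: decision tree only


class DegenerateRangeError(ValueError):
    """lower == upper: the range collapses; treat the parameter as fixed."""


@dataclass(frozen=True)
class Parameter:
    name: str
    base: float
    lower: float | None = None
    upper: float | None = None
    dist: str = "fixed"

    def __post_init__(self):
        if self.dist not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.dist!r} for {self.name}")
        if self.lower is not None and self.upper is not None:
            if not (self.lower <= self.base <= self.upper):
                raise ValueError(
                    f"{self.name}: bounds ({self.lower}, {self.upper}) must "
                    f"bracket base {self.base}"
                )
        if self.dist not in ("fixed",) and (self.lower is None or self.upper is None):
            raise ValueError(f"{self.name}: non-fixed parameter needs both bounds")

    @property
    def varied(self) -> bool:
        return self.dist != "fixed"


class ParameterSet:
    """Ordered, name-unique collection of parameters."""

    def __init__(self, parameters):
        self._params: dict[str, Parameter] = {}
        for p in parameters:
            if p.name in self._params:
                raise ValueError(f"duplicate parameter name {p.name!r}")
            self._params[p.name] = p

    def __iter__(self):
        return iter(self._params.values())

    def __len__(self):
        return len(self._params)

    def __contains__(self, name):
        return name in self._params

    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def base_values(self) -> dict[str, float]:
        return {p.name: p.base for p in self}

    def varied(self) -> list[Parameter]:
        return [p for p in self if p.varied]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": p.name,
                    "base": p.base,
                    "lower": p.lower,
                    "upper": p.upper,
                    "dist": p.dist,
                }
                for p in self
            ]
        )

    def __eq__(self, other):
        return isinstance(other, ParameterSet) and self._params == other._params


# --------------------------------------------------------------------------
# samplers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerSpec:
    family: str
    args: tuple

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "gamma":
            shape, scale = self.args
            return rng.gamma(shape, scale, size=size)
        if self.family == "beta":
            a, b = self.args
            return rng.beta(a, b, size=size)
        if self.family == "lognormal":
            meanlog, sdlog = self.args
            return rng.lognormal(meanlog, sdlog, size=size)
        if self.family == "uniform":
            lo, hi = self.args
            return rng.uniform(lo, hi, size=size)
        raise ValueError(f"cannot sample family {self.family!r}")


def parameterize(param: Parameter) -> SamplerSpec:
    """Method-of-moments sampler for a non-fixed parameter (see module
    docstring for the conversions)."""
    if not param.varied:
        raise ValueError(f"{param.name} is fixed and is never sampled")
    lo, hi = float(param.lower), float(param.upper)
    if hi == lo:
        raise DegenerateRangeError(
            f"{param.name}: lower == upper == {lo}; collapse to fixed"
        )
    if param.dist == "uniform":
        return SamplerSpec("uniform", (lo, hi))
    se = (hi - lo) / 3.92
    base = float(param.base)
    if param.dist == "gamma":
        if base <= 0:
            raise ValueError(f"{param.name}: gamma base must be > 0")
        return SamplerSpec("gamma", ((base / se) ** 2, se**2 / base))
    if param.dist == "beta":
        if not 0.0 < base < 1.0:
            raise ValueError(f"{param.name}: beta base must lie in (0, 1)")
        nu = base * (1.0 - base) / se**2 - 1.0
        if nu <= 0:
            raise ValueError(f"{param.name}: range too wide for a beta fit")
        return SamplerSpec("beta", (base * nu, (1.0 - base) * nu))
    if param.dist == "lognormal":
        if base <= 0 or lo <= 0:
            raise ValueError(f"{param.name}: lognormal needs positive values")
        return SamplerSpec("lognormal", (np.log(base), (np.log(hi) - np.log(lo)) / 3.92))
    raise ValueError(f"unknown distribution {param.dist!r}")


# --------------------------------------------------------------------------
# parameter table -> model inputs
# --------------------------------------------------------------------------

HR_NAMES = tuple(f"hr_mrs{k}" for k in range(6))
RECURRENCE_NAMES = tuple(f"recurrence_y{k}" for k in range(1, 10)) + (
    "recurrence_y10plus",
)
UTILITY_NAMES = tuple(f"utility_mrs{k}" for k in range(6))


def model_inputs_from_values(
    values: dict,
) -> tuple[CostSet, UtilitySet, MortalityHRs, RecurrenceSchedule, float, float]:
    """Translate a named parameter-value mapping into the model's typed
    inputs; returns (costs, utilities, HRs, recurrence schedule,
    cost discount rate, utility discount rate)."""
    costs = CostSet(
        edsl_unit=values["cost_edsl_tablet"],
        edcsi_unit=values["cost_edcsi_vial"],
        drip_unit=values["cost_iv_drip"],
        bun_unit=values["cost_bun"],
        creatinine_unit=values["cost_creatinine"],
        monitor_freq=values["monitoring_frequency"],
        hosp_mrs02=values["cost_hospitalization_mrs02"],
        hosp_mrs35=values["cost_hospitalization_mrs35"],
        hosp_mrs6=values["cost_hospitalization_mrs6"],
        annual_mrs02=values["cost_poststroke_mrs02"],
        annual_mrs35=values["cost_poststroke_mrs35"],
    )
    utils = UtilitySet(
        by_state=tuple(values[n] for n in UTILITY_NAMES),
        disutility_stroke=values["disutility_stroke"],
        disutility_drip=values["disutility_drip"],
    )
    hrs = MortalityHRs(by_state=tuple(values[n] for n in HR_NAMES))
    recurrence = RecurrenceSchedule(
        annual=tuple(values[n] for n in RECURRENCE_NAMES)
    )
    return (
        costs,
        utils,
        hrs,
        recurrence,
        values["discount_rate_cost"],
        values["discount_rate_utility"],
    )


def _draw_valid(values: dict) -> bool:
    for n in UTILITY_NAMES:
        if not 0.0 <= values[n] <= 1.0:
            return False
    for n in ("disutility_stroke", "disutility_drip"):
        if not 0.0 <= values[n] <= 1.0:
            return False
    for n in HR_NAMES:
        if values[n] <= 0:
            return False
    for n in values:
        if n.startswith("cost_") and values[n] < 0:
            return False
    for n in ("discount_rate_cost", "discount_rate_utility"):
        if not 0.0 <= values[n] <= 0.08:
            return False
    return values["monitoring_frequency"] >= 0


# --------------------------------------------------------------------------
# the model closure
# --------------------------------------------------------------------------

class ModelPipeline:
    """The full evaluation pipeline downstream of weighting, closed over
    the day-90 mRS distributions, the life table and the post-recurrence
    distribution.  Calling it with a parameter-value mapping returns a
    :class:`CEResult`; this is the single entry point DSA, PSA and the
    scenario grid re-run."""

    def __init__(
        self,
        day90_edsl: MRSDistribution,
        day90_edcsi: MRSDistribution,
        life_table,
        post_recur: PostRecurrenceDistribution = PostRecurrenceDistribution(),
        horizon: float = 40,
        start_age: float = 60.0,
        half_cycle: bool = True,
        wtp: float = GDP_PER_CAPITA_2024,
        lifetime_poststroke: bool = False,
    ):
        self.day90_edsl = day90_edsl
        self.day90_edcsi = day90_edcsi
        self.life_table = life_table
        self.post_recur = post_recur
        self.horizon = horizon
        self.start_age = start_age
        self.half_cycle = half_cycle
        self.wtp = wtp
        self.lifetime_poststroke = lifetime_poststroke

    def __call__(self, values: dict) -> CEResult:
        shorts = {
            "EDSL": run_decision_tree("EDSL", self.day90_edsl),
            "EDCSI": run_decision_tree("EDCSI", self.day90_edcsi),
        }
        costs, utils, hrs, recurrence, rc, ru = model_inputs_from_values(values)

        if self.horizon == TREE_ONLY_HORIZON:
            a = accrue_tree_only(shorts["EDSL"], costs, utils)
            b = accrue_tree_only(shorts["EDCSI"], costs, utils)
            return compare(a, b, self.wtp)

        spec = ModelSpec(
            start_age=self.start_age,
            horizon=int(self.horizon),
            discount_rate_cost=rc,
            discount_rate_utility=ru,
            half_cycle=self.half_cycle,
        )
        # transition matrices are arm-independent: build once per draw
        mats = transition_matrices(
            spec, self.life_table, hrs, recurrence, self.post_recur
        )
        accruals = {}
        for arm, short in shorts.items():
            trace = run_markov(
                short.day90, spec, self.life_table, hrs, recurrence,
                self.post_recur, matrices=mats,
            )
            accruals[arm] = accrue(
                trace, short, costs, utils, spec,
                lifetime_poststroke=self.lifetime_poststroke,
            )
        return compare(accruals["EDSL"], accruals["EDCSI"], self.wtp)


# --------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    outcome_at_lower: float
    outcome_at_upper: float
    metric: str  # "icer" or "nmb"
    failed: bool = False

    @property
    def spread(self) -> float:
        return abs(self.outcome_at_upper - self.outcome_at_lower)


def run_dsa(model: ModelPipeline, params: ParameterSet) -> list[TornadoEntry]:
    """One-way DSA: re-run the pipeline at each varied parameter's bounds,
    all else at base.

    The reported outcome is the ICER; when the QALY increment changes sign
    within an entry (so the ICER is not comparable across the two bounds)
    the entry falls back to the incremental net monetary benefit at the
    pipeline's WTP.  Entries come back sorted by descending spread; a bound
    at which the model fails is flagged, never dropped.
    """
    base = params.base_values()
    entries = []
    for p in params.varied():
        outs = {}
        failed = False
        for bound, value in (("lower", p.lower), ("upper", p.upper)):
            values = dict(base)
            values[p.name] = value
            try:
                outs[bound] = model(values)
            except Exception:
                failed = True
                outs[bound] = None
        if failed:
            entries.append(TornadoEntry(p.name, np.nan, np.nan, "icer", True))
            continue
        lo_r, hi_r = outs["lower"], outs["upper"]
        sign_flip = (
            lo_r.icer is None
            or hi_r.icer is None
            or np.sign(lo_r.delta_qalys) != np.sign(hi_r.delta_qalys)
        )
        if sign_flip:
            entries.append(
                TornadoEntry(p.name, lo_r.nmb_difference, hi_r.nmb_difference, "nmb")
            )
        else:
            entries.append(TornadoEntry(p.name, lo_r.icer, hi_r.icer, "icer"))
    return sorted(entries, key=lambda e: (not e.failed, e.spread), reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "outcome_at_lower": e.outcome_at_lower,
                "outcome_at_upper": e.outcome_at_upper,
                "spread": e.spread,
                "metric": e.metric,
                "failed": e.failed,
            }
            for e in entries
        ]
    )


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis
# --------------------------------------------------------------------------

def run_psa(
    model: ModelPipeline,
    params: ParameterSet,
    n_iter: int = 5000,
    seed: int = 0,
    max_rejection_rate: float = 0.01,
) -> pd.DataFrame:
    """Monte-Carlo PSA: per iteration, draw every non-fixed parameter from
    its method-of-moments sampler, re-run the pipeline, and record the
    increments.

    Draws that land outside a parameter's valid domain (for example a
    utility above one) are rejected and redrawn; the run aborts if more
    than ``max_rejection_rate`` of attempted draws are rejected.  A fixed
    seed makes the output table bit-identical across runs.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    base = params.base_values()
    samplers = {p.name: parameterize(p) for p in params.varied()}

    rows = []
    rejected = 0
    for i in range(n_iter):
        for _attempt in range(100):
            values = dict(base)
            for name, sampler in samplers.items():
                values[name] = float(sampler.sample(rng))
            if _draw_valid(values):
                break
            rejected += 1
        else:
            raise RuntimeError("could not draw a valid parameter vector")
        res = model(values)
        row = {
            "iteration": i,
            "delta_cost": res.delta_cost,
            "delta_qalys": res.delta_qalys,
            "cost_edsl": res.edsl.total_cost,
            "cost_edcsi": res.edcsi.total_cost,
            "qalys_edsl": res.edsl.total_qalys,
            "qalys_edcsi": res.edcsi.total_qalys,
        }
        row.update({name: values[name] for name in samplers})
        rows.append(row)

    attempts = n_iter + rejected
    if rejected / attempts > max_rejection_rate:
        raise RuntimeError(
            f"PSA rejection rate {rejected / attempts:.2%} exceeds "
            f"{max_rejection_rate:.0%}"
        )
    out = pd.DataFrame(rows)
    out.attrs["rejected_draws"] = rejected
    return out


@dataclass(frozen=True)
class CEACCurve:
    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


DEFAULT_WTP_GRID = np.arange(0, 300_001, 5000, dtype=float)


def compute_ceac(
    psa: pd.DataFrame, wtp_grid: np.ndarray = DEFAULT_WTP_GRID
) -> CEACCurve:
    """Probability the sublingual arm is cost-effective at each WTP:
    the share of iterations with positive net monetary benefit
    ``wtp * dE - dC``."""
    if len(psa) == 0:
        raise ValueError("PSA output is empty")
    grid = np.asarray(wtp_grid, dtype=float)
    de = psa["delta_qalys"].to_numpy()
    dc = psa["delta_cost"].to_numpy()
    prob = np.array([(w * de - dc > 0).mean() for w in grid])
    return CEACCurve(wtp=grid, probability=prob)


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------

DEFAULT_SCENARIO_HORIZONS = (TREE_ONLY_HORIZON, 5, 10, 20, 30, 40)


def run_scenarios(
    day90_by_estimand: dict,
    params: ParameterSet,
    life_table,
    post_recur: PostRecurrenceDistribution = PostRecurrenceDistribution(),
    horizons=DEFAULT_SCENARIO_HORIZONS,
    estimands=("ATE", "ATT"),
    wtp: float = GDP_PER_CAPITA_2024,
) -> pd.DataFrame:
    """Base-case re-runs over a (horizon x estimand) grid.

    ``day90_by_estimand`` maps each estimand name to its pair of weighted
    day-90 distributions (EDSL, EDCSI).  Horizon 0.25 denotes the 90-day
    decision-tree-only scenario; other horizons are whole years.
    """
    base = params.base_values()
    rows = []
    for estimand in estimands:
        if estimand not in day90_by_estimand:
            raise ValueError(f"unknown estimand {estimand!r}")
        d_edsl, d_edcsi = day90_by_estimand[estimand]
        for h in horizons:
            if h != TREE_ONLY_HORIZON and (h < 1 or h != int(h)):
                raise ValueError(f"horizon must be 0.25 or a whole year, got {h}")
            model = ModelPipeline(
                d_edsl, d_edcsi, life_table, post_recur, horizon=h, wtp=wtp
            )
            res = model(base)
            rows.append(
                {
                    "estimand": estimand,
                    "horizon_years": h,
                    "delta_cost": res.delta_cost,
                    "delta_qalys": res.delta_qalys,
                    "icer": res.icer,
                    "label": res.label,
                }
            )
    return pd.DataFrame(rows)
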