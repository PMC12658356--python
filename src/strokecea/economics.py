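"""Cost and QALY accrual, discounting, and incremental comparison.

Costs are direct medical costs only (2024 Chinese Yuan): the 14-day drug
course, IV administration (injectable arm only), renal-function
monitoring, hospitalization (one initial stay banded by the day-90 mRS, and
one stay per recurrent stroke banded by the destination state, with the
mRS 6 band for fatal recurrences), and post-stroke care banded mRS 0-2 vs
3-5.  Post-stroke care is charged over the first post-acute year (the
275-day bridge window); routine maintenance care in later years is outside
the costing scope, whereas recurrent strokes keep generating
hospitalization charges for life.  A ``lifetime_poststroke`` switch
instead accrues the banded annual cost on half-cycle-corrected occupancy
every cycle.  Health outcomes are quality-adjusted life-years from
EQ-5D utilities by mRS state, minus a one-time disutility per recurrent
stroke and a one-time IV-drip disutility in the injectable arm.

Both streams discount at 5 % per year.  The first model year (the 90-day
tree plus the 275-day bridging remainder) is undiscounted; the flow of
year ``t >= 2`` carries the factor ``(1 + r)^-(t-1)``.  State occupancy in
Markov cycles is half-cycle corrected by the trapezoid of successive
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import (
    BRIDGE_FRACTION,
    DEAD,
    TREE_FRACTION,
    ModelSpec,
    ShortTermResult,
    Trace,
)

GDP_PER_CAPITA_2024 = 95_749.0  # CNY; 1x willingness-to-pay anchor
WTP_HIGH = 3 * GDP_PER_CAPITA_2024  # 287,247


@dataclass(frozen=True)
class CostSet:
    """Unit costs, 2024 CNY."""

    edsl_unit: float = 70.0  # per tablet
    edcsi_unit: float = 29.68  # per vial
    vials_per_administration: int = 3  # 37.5 mg dose over 12.5 mg vials
    drip_unit: float = 8.11  # per IV administration
    bun_unit: float = 6.28  # blood urea nitrogen test
    creatinine_unit: float = 6.51  # serum creatinine test
    monitor_freq: float = 1.0  # renal panels per week
    hosp_mrs02: float = 12_995.74
    hosp_mrs35: float = 17_744.26
    hosp_mrs6: float = 14_373.51
    annual_mrs02: float = 9_544.86
    annual_mrs35: float = 14_669.48

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if float(getattr(self, name)) < 0:
                raise ValueError(f"cost field {name} must be non-negative")


@dataclass(frozen=True)
class UtilitySet:
    """EQ-5D utilities by mRS state and the two event disutilities."""

    by_state: tuple = (0.983, 0.894, 0.679, 0.556, 0.270, 0.058)
    disutility_stroke: float = 0.086  # per recurrence event
    disutility_drip: float = 0.023  # one-time, injectable arm

    def __post_init__(self):
        u = tuple(float(v) for v in self.by_state)
        if len(u) != 6 or any(not 0.0 <= v <= 1.0 for v in u):
            raise ValueError("need 6 state utilities in [0, 1] (mRS 0-5)")
        if self.disutility_stroke < 0 or self.disutility_drip < 0:
            raise ValueError("disutilities must be non-negative")
        object.__setattr__(self, "by_state", u)

    def vector(self) -> np.ndarray:
        """Utility over the 8 model states (bookkeeping and dead are 0)."""
        v = np.zeros(8)
        v[0:6] = self.by_state
        return v


COST_COMPONENTS = (
    "drug",
    "administration",
    "monitoring",
    "hospitalization",
    "post_stroke",
)


@dataclass(frozen=True)
class ArmAccrual:
    """Discounted totals for one arm."""

    arm: str
    cost_components: dict  # keyed by COST_COMPONENTS
    total_cost: float
    state_utility_qalys: float
    disutility_qalys: float  # reported as a negative number
    total_qalys: float

    def __post_init__(self):
        gap = abs(sum(self.cost_components.values()) - self.total_cost)
        if gap > 1e-6:
            raise ValueError(f"cost components do not sum to total (gap {gap})")


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison (EDSL minus EDCSI)."""

    edsl: ArmAccrual
    edcsi: ArmAccrual
    delta_cost: float
    delta_qalys: float
    icer: float | None  # None when delta_qalys == 0
    label: str  # dominant / dominated / trade-off-CE / trade-off-not-CE
    equal_effect: bool
    wtp: float
    nmb_difference: float  # wtp * dE - dC

    def to_frame(self) -> pd.DataFrame:
        rows = [("Costs", self.edsl.total_cost, self.edcsi.total_cost,
                 self.delta_cost)]
        names = {
            "drug": "Drug costs",
            "administration": "Administration costs",
            "monitoring": "Renal function monitoring costs",
            "hospitalization": "Hospitalization costs",
            "post_stroke": "Post-stroke costs",
        }
        for key in COST_COMPONENTS:
            a = self.edsl.cost_components[key]
            b = self.edcsi.cost_components[key]
            rows.append((names[key], a, b, a - b))
        rows.append(("QALYs", self.edsl.total_qalys, self.edcsi.total_qalys,
                     self.delta_qalys))
        rows.append(("Health status utility", self.edsl.state_utility_qalys,
                     self.edcsi.state_utility_qalys,
                     self.edsl.state_utility_qalys - self.edcsi.state_utility_qalys))
        rows.append(("Disutility", self.edsl.disutility_qalys,
                     self.edcsi.disutility_qalys,
                     self.edsl.disutility_qalys - self.edcsi.disutility_qalys))
        frame = pd.DataFrame(rows, columns=["component", "EDSL", "EDCSI", "increment"])
        frame.loc[len(frame)] = ["ICER", np.nan, np.nan,
                                 np.nan if self.icer is None else self.icer]
        frame.loc[len(frame)] = ["Result", "", "", self.label]
        return frame


# --------------------------------------------------------------------------
# discounting
# --------------------------------------------------------------------------

def discount_factor(rate: float, cycle: int) -> float:
    """Discount factor for the flow of model cycle ``cycle``.

    Year 1 (the tree window plus the cycle-0 bridge) is undiscounted; the
    flow of cycle ``t >= 1`` carries ``(1 + rate)^-(t - 1)``.
    """
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    if cycle <= 1:
        return 1.0
    return float((1.0 + rate) ** -(cycle - 1))


# --------------------------------------------------------------------------
# component costs
# --------------------------------------------------------------------------

def course_drug_cost(arm: str, costs: CostSet) -> tuple[float, float]:
    """(drug cost, administration cost) of the 14-day twice-daily course.

    EDSL: one tablet per dose, 28 doses, no administration fee.
    EDCSI: three vials per dose, 28 doses, plus 28 IV drip fees.
    """
    if arm == "EDSL":
        return costs.edsl_unit * 28.0, 0.0
    if arm == "EDCSI":
        return (
            costs.edcsi_unit * costs.vials_per_administration * 28.0,
            costs.drip_unit * 28.0,
        )
    raise ValueError(f"unknown arm {arm!r}")


def monitoring_cost(costs: CostSet, weeks: int = 2) -> float:
    """Weekly renal panel (urea nitrogen + creatinine) over the course."""
    return (costs.bun_unit + costs.creatinine_unit) * costs.monitor_freq * weeks


def _band_costs(costs: CostSet) -> np.ndarray:
    """Annual post-stroke cost over the 8 model states."""
    v = np.zeros(8)
    v[0:3] = costs.annual_mrs02
    v[3:6] = costs.annual_mrs35
    return v


def _hosp_by_day90_band(day90: np.ndarray, costs: CostSet) -> float:
    return float(
        day90[0:3].sum() * costs.hosp_mrs02
        + day90[3:6].sum() * costs.hosp_mrs35
        + day90[6] * costs.hosp_mrs6
    )


# --------------------------------------------------------------------------
# accrual
# --------------------------------------------------------------------------

def _half_cycle_occupancy(trace: Trace, half_cycle: bool) -> np.ndarray:
    """Per-cycle credited occupancy for cycles 1..H: trapezoid of the
    bounding boundaries when half-cycle correction is on, else the
    end-of-cycle boundary."""
    occ = trace.occupancy
    if half_cycle:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[1:]


def accrue(
    trace: Trace,
    short: ShortTermResult,
    costs: CostSet,
    utils: UtilitySet,
    spec: ModelSpec,
    lifetime_poststroke: bool = False,
) -> ArmAccrual:
    """Discounted lifetime costs and QALYs for one arm.

    The day-90 distribution is held over the whole tree window (90/365 of a
    year) and over the bridge (275/365); Markov cycles accrue QALYs on
    half-cycle corrected occupancy.  One-time charges: the course costs and
    the initial hospitalization at entry, a hospitalization per expected
    recurrence at its cycle's discount factor, and the drip disutility at
    time zero.  Post-stroke care cost covers the bridge window only unless
    ``lifetime_poststroke`` extends it to every cycle.
    """
    if trace.horizon != spec.horizon:
        raise ValueError(
            f"trace horizon {trace.horizon} != spec horizon {spec.horizon}"
        )
    day90 = short.day90.p
    rc, ru = spec.discount_rate_cost, spec.discount_rate_utility
    h = spec.horizon

    drug, admin = course_drug_cost(short.arm, costs)
    monitor = monitoring_cost(costs, short.monitoring_weeks)
    hosp = _hosp_by_day90_band(day90, costs)

    state_cost = _band_costs(costs)
    u = utils.vector()
    occ0 = trace.occupancy[0]

    post_stroke = BRIDGE_FRACTION * float(occ0 @ state_cost)
    qaly_states = (TREE_FRACTION + BRIDGE_FRACTION) * float(occ0 @ u)
    qaly_dis = utils.disutility_drip if short.drip_disutility_applies else 0.0

    if h >= 1:
        credited = _half_cycle_occupancy(trace, spec.half_cycle)
        hosp_band = np.array([costs.hosp_mrs02, costs.hosp_mrs35, costs.hosp_mrs6])
        for t in range(1, h + 1):
            dfc = discount_factor(rc, t)
            dfu = discount_factor(ru, t)
            if lifetime_poststroke:
                post_stroke += dfc * float(credited[t - 1] @ state_cost)
            qaly_states += dfu * float(credited[t - 1] @ u)
            hosp += dfc * float(trace.recurrences_by_band[t] @ hosp_band)
            qaly_dis += dfu * utils.disutility_stroke * trace.recurrences[t]

    components = {
        "drug": drug,
        "administration": admin,
        "monitoring": monitor,
        "hospitalization": hosp,
        "post_stroke": post_stroke,
    }
    return ArmAccrual(
        arm=short.arm,
        cost_components=components,
        total_cost=sum(components.values()),
        state_utility_qalys=qaly_states,
        disutility_qalys=-qaly_dis,
        total_qalys=qaly_states - qaly_dis,
    )


def accrue_tree_only(
    short: ShortTermResult, costs: CostSet, utils: UtilitySet
) -> ArmAccrual:
    """90-day-only accrual: the decision tree with no Markov phase, no
    discounting and no recurrence."""
    drug, admin = course_drug_cost(short.arm, costs)
    monitor = monitoring_cost(costs, short.monitoring_weeks)
    hosp = _hosp_by_day90_band(short.day90.p, costs)
    u = np.concatenate([np.asarray(utils.by_state), [0.0]])
    qaly_states = TREE_FRACTION * float(short.day90.p @ u)
    qaly_dis = utils.disutility_drip if short.drip_disutility_applies else 0.0
    components = {
        "drug": drug,
        "administration": admin,
        "monitoring": monitor,
        "hospitalization": hosp,
        "post_stroke": 0.0,
    }
    return ArmAccrual(
        arm=short.arm,
        cost_components=components,
        total_cost=sum(components.values()),
        state_utility_qalys=qaly_states,
        disutility_qalys=-qaly_dis,
        total_qalys=qaly_states - qaly_dis,
    )


# --------------------------------------------------------------------------
# incremental comparison
# --------------------------------------------------------------------------

def compare(
    result_edsl: ArmAccrual,
    result_edcsi: ArmAccrual,
    wtp: float = GDP_PER_CAPITA_2024,
) -> CEResult:
    """Incremental cost-effectiveness of EDSL vs EDCSI.

    Dominance labels: ``dominant`` when EDSL gains QALYs at lower cost,
    ``dominated`` for the reverse; trade-offs are classified by net
    monetary benefit at the given willingness-to-pay (``trade-off-CE`` when
    ``wtp * dE - dC > 0``).  With exactly equal effects the ICER is
    undefined and the label is decided on cost alone, flagged
    ``equal_effect``.
    """
    d_cost = result_edsl.total_cost - result_edcsi.total_cost
    d_qaly = result_edsl.total_qalys - result_edcsi.total_qalys
    nmb = wtp * d_qaly - d_cost

    equal_effect = d_qaly == 0.0
    icer = None if equal_effect else d_cost / d_qaly

    if equal_effect:
        label = "dominant" if d_cost < 0 else (
            "dominated" if d_cost > 0 else "trade-off-CE"
        )
    elif d_qaly > 0 and d_cost < 0:
        label = "dominant"
    elif d_qaly < 0 and d_cost > 0:
        label = "dominated"
    else:
        label = "trade-off-CE" if nmb > 0 else "trade-off-not-CE"

    return CEResult(
        edsl=result_edsl,
        edcsi=result_edcsi,
        delta_cost=d_cost,
        delta_qalys=d_qaly,
        icer=icer,
        label=label,
        equal_effect=equal_effect,
        wtp=wtp,
        nmb_difference=nmb,
    )
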