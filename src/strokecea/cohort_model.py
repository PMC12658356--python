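"""Short-term decision tree and long-term Markov cohort model.

Patients enter a 90-day decision tree whose endpoint — the day-90 mRS
distribution of each arm — becomes the initial state vector of a lifetime
Markov cohort model over health states mRS 0-5 plus an absorbing death
state.  A bridging cycle (cycle 0) holds the day-90 distribution for the
remaining 275/365 of the first year without transitions or discounting;
annual cycles then run to the horizon (default 40 years from a starting age
of 60).

Within each annual cycle events resolve in a fixed order:

1. death, with the age-specific all-cause probability scaled on the hazard
   scale by the mRS-specific hazard ratio, ``p = 1 - (1 - q)**hr``;
2. among survivors, a recurrent ischemic stroke with a year-since-stroke
   probability applied uniformly across alive states; recurrers move to a
   state of equal or greater disability, drawn from the post-recurrence
   distribution truncated at the current state and renormalized (mass on
   mRS 6 adds to death);
3. non-recurrers remain in their state.

Recurrence is a within-cycle event with destination redistribution rather
than a persistent occupancy state; the expected event counts (by
destination cost band) are recorded per cycle so the economics layer can
attach one-time costs and disutilities.  State index 6 is reserved for that
event bookkeeping and always carries zero occupancy at cycle boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .weighting import MRSDistribution

N_STATES = 8
ALIVE = slice(0, 6)  # mRS 0..5
RECURRENT = 6  # transient bookkeeping slot, zero occupancy at boundaries
DEAD = 7

DAYS_DECISION_TREE = 90
DAYS_PER_YEAR = 365
BRIDGE_FRACTION = (DAYS_PER_YEAR - DAYS_DECISION_TREE) / DAYS_PER_YEAR
TREE_FRACTION = DAYS_DECISION_TREE / DAYS_PER_YEAR


@dataclass(frozen=True)
class ModelSpec:
    """Global settings of the cohort simulation."""

    start_age: float = 60.0
    cycle_length: float = 1.0  # years
    horizon: int = 40  # annual cycles after the bridging cycle
    discount_rate_cost: float = 0.05
    discount_rate_utility: float = 0.05
    half_cycle: bool = True

    def __post_init__(self):
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        for r in (self.discount_rate_cost, self.discount_rate_utility):
            if not 0.0 <= r <= 0.08:
                raise ValueError(
                    f"discount rates must lie in [0, 0.08], got {r}"
                )


@dataclass(frozen=True)
class RecurrenceSchedule:
    """Annual recurrent-stroke probability by year since the index stroke.

    ``annual[i]`` covers year ``i + 1``; lookups beyond the table return the
    terminal (10-years-and-above) value.
    """

    annual: tuple = (
        0.059, 0.036, 0.025, 0.022, 0.022, 0.027, 0.027, 0.023, 0.028, 0.016,
    )

    def __post_init__(self):
        a = tuple(float(v) for v in self.annual)
        if len(a) == 0 or any(not 0.0 <= v <= 1.0 for v in a):
            raise ValueError("recurrence probabilities must lie in [0, 1]")
        object.__setattr__(self, "annual", a)

    def prob(self, year_since_stroke: int) -> float:
        if year_since_stroke < 1:
            raise ValueError("year since stroke starts at 1")
        return self.annual[min(year_since_stroke, len(self.annual)) - 1]


@dataclass(frozen=True)
class MortalityHRs:
    """Excess-mortality hazard ratios vs the general population per alive
    mRS state."""

    by_state: tuple = (1.53, 1.52, 2.17, 3.18, 4.55, 6.55)

    def __post_init__(self):
        hr = tuple(float(v) for v in self.by_state)
        if len(hr) != 6 or any(v <= 0 for v in hr):
            raise ValueError("need 6 positive hazard ratios (mRS 0-5)")
        object.__setattr__(self, "by_state", hr)


@dataclass(frozen=True)
class PostRecurrenceDistribution:
    """Destination mRS distribution after a recurrent stroke, before
    conditioning on 'equal or greater disability'.

    The default is a synthetic placeholder shaped like a moderately severe
    recurrent-stroke outcome; any seven-probability vector drops in.
    """

    p: tuple = (0.08, 0.16, 0.18, 0.20, 0.15, 0.10, 0.13)

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (7,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("post-recurrence distribution must be 7 probabilities summing to 1")
        object.__setattr__(self, "p", tuple(p / p.sum()))

    def truncated(self, state: int) -> np.ndarray:
        """Distribution conditioned on destination >= ``state`` (equal or
        greater disability).  If the conditional mass vanishes the patient
        stays put: the mass is returned as a point mass at ``state``."""
        p = np.asarray(self.p, dtype=float).copy()
        p[:state] = 0.0
        total = p.sum()
        if total <= 0.0:
            p[:] = 0.0
            p[state] = 1.0
            return p
        return p / total


@dataclass(frozen=True)
class Trace:
    """Cohort trace: state occupancy at every cycle boundary plus per-cycle
    expected event counts.

    ``occupancy`` has ``horizon + 1`` rows over the 8 model states; row 0 is
    the bridged day-90 distribution.  ``recurrences_by_band`` splits each
    cycle's expected recurrent strokes by destination cost band
    (mRS 0-2, mRS 3-5, fatal).
    """

    occupancy: np.ndarray  # (horizon+1, 8)
    ages: np.ndarray  # attained age at each boundary
    recurrences: np.ndarray  # (horizon+1,), index = cycle, entry 0 is 0
    recurrences_by_band: np.ndarray  # (horizon+1, 3): to mRS0-2, 3-5, death
    deaths: np.ndarray  # (horizon+1,), expected deaths during each cycle

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        cols = [f"mrs{k}" for k in range(6)] + ["recurrent", "dead"]
        frame = pd.DataFrame(self.occupancy, columns=cols)
        frame.insert(0, "cycle", np.arange(self.horizon + 1))
        frame.insert(1, "age", self.ages)
        frame["expected_recurrences"] = self.recurrences
        frame["expected_deaths"] = self.deaths
        return frame


@dataclass(frozen=True)
class ShortTermResult:
    """Decision-tree endpoint for one arm: the day-90 state distribution
    and the arm-specific short-term resource-use flags the economics layer
    prices."""

    arm: str
    day90: MRSDistribution
    drug_administrations: int  # dosing events over the 14-day course
    iv_administrations: int  # IV drip events (EDCSI only)
    monitoring_weeks: int  # weeks of renal-function monitoring
    drip_disutility_applies: bool

    def initial_state_vector(self) -> np.ndarray:
        """Map the day-90 mRS distribution onto the 8 model states (mRS 6
        mass enters already dead)."""
        v = np.zeros(N_STATES)
        v[0:6] = self.day90.p[0:6]
        v[DEAD] = self.day90.p[6]
        return v


# --------------------------------------------------------------------------
# transition construction
# --------------------------------------------------------------------------

def adjust_annual_probability(q: float, hr: float) -> float:
    """Apply a hazard ratio to an annual probability on the rate scale:
    ``p = 1 - (1 - q)**hr``, capped at 1."""
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"annual probability must lie in [0, 1], got {q}")
    if q >= 1.0:
        return 1.0
    return min(1.0, 1.0 - (1.0 - q) ** hr)


def build_transition_matrix(
    cycle: int,
    current_age: float,
    life_table,
    hrs: MortalityHRs,
    recurrence: RecurrenceSchedule,
    post_recur: PostRecurrenceDistribution,
) -> np.ndarray:
    """One-cycle 8x8 transition matrix at the given attained age.

    Event order within the cycle: death first, then recurrence among
    survivors with destination 'equal or greater disability', then
    remaining in state.  Rows sum to one; the dead row is the identity row;
    the bookkeeping state maps to itself and never receives mass.
    """
    if cycle < 1:
        raise ValueError("Markov cycles start at 1")
    q = life_table.q(current_age)
    p_rec = recurrence.prob(cycle)

    m = np.zeros((N_STATES, N_STATES))
    for s in range(6):
        p_die = adjust_annual_probability(q, hrs.by_state[s])
        survive = 1.0 - p_die
        dest = post_recur.truncated(s)
        m[s, DEAD] = p_die + survive * p_rec * dest[6]
        m[s, 0:6] += survive * p_rec * dest[0:6]
        m[s, s] += survive * (1.0 - p_rec)
    m[RECURRENT, RECURRENT] = 1.0
    m[DEAD, DEAD] = 1.0
    return m


def transition_matrices(
    spec: ModelSpec,
    life_table,
    hrs: MortalityHRs,
    recurrence: RecurrenceSchedule,
    post_recur: PostRecurrenceDistribution,
) -> list[np.ndarray]:
    """All per-cycle matrices for a run; arms share these, so callers
    evaluating both arms under one parameter draw build them once."""
    return [
        build_transition_matrix(
            t, spec.start_age + t * spec.cycle_length, life_table, hrs,
            recurrence, post_recur,
        )
        for t in range(1, spec.horizon + 1)
    ]


# --------------------------------------------------------------------------
# model runs
# --------------------------------------------------------------------------

def run_decision_tree(arm: str, mrs90: MRSDistribution) -> ShortTermResult:
    """90-day decision tree for one arm.

    Both regimens run twice daily for 14 days (28 dosing events); only the
    injectable arm incurs IV administrations, and its 30-minute drips carry
    a one-time disutility.  Renal function is monitored weekly over the
    2-week course in both arms.
    """
    if arm not in ("EDSL", "EDCSI"):
        raise ValueError(f"unknown arm {arm!r}")
    iv = 28 if arm == "EDCSI" else 0
    return ShortTermResult(
        arm=arm,
        day90=mrs90,
        drug_administrations=28,
        iv_administrations=iv,
        monitoring_weeks=2,
        drip_disutility_applies=(arm == "EDCSI"),
    )


def run_markov(
    initial: MRSDistribution | np.ndarray,
    spec: ModelSpec,
    life_table,
    hrs: MortalityHRs = MortalityHRs(),
    recurrence: RecurrenceSchedule = RecurrenceSchedule(),
    post_recur: PostRecurrenceDistribution = PostRecurrenceDistribution(),
    matrices: list[np.ndarray] | None = None,
) -> Trace:
    """Propagate the cohort from the bridged day-90 distribution to the
    horizon, recording occupancy at every boundary and expected event
    counts per cycle.

    ``matrices`` may carry precomputed per-cycle transition matrices (they
    are arm-independent); otherwise they are built here.
    """
    if isinstance(initial, MRSDistribution):
        v0 = np.zeros(N_STATES)
        v0[0:6] = initial.p[0:6]
        v0[DEAD] = initial.p[6]
    else:
        v0 = np.asarray(initial, dtype=float)
        if v0.shape != (N_STATES,) or abs(v0.sum() - 1.0) > 1e-9:
            raise ValueError("initial state vector must be 8 probabilities summing to 1")

    h = spec.horizon
    if matrices is None:
        matrices = transition_matrices(spec, life_table, hrs, recurrence, post_recur)
    elif len(matrices) < h:
        raise ValueError("fewer precomputed matrices than horizon cycles")

    occ = np.zeros((h + 1, N_STATES))
    occ[0] = v0
    rec = np.zeros(h + 1)
    rec_band = np.zeros((h + 1, 3))
    deaths = np.zeros(h + 1)

    q_by_state = np.empty(6)
    for t in range(1, h + 1):
        m = matrices[t - 1]
        occ[t] = occ[t - 1] @ m
        # expected events, consistent with the matrix's internal event order
        age = spec.start_age + t * spec.cycle_length
        q = life_table.q(age)
        p_rec = recurrence.prob(t)
        for s in range(6):
            q_by_state[s] = adjust_annual_probability(q, hrs.by_state[s])
        survivors = occ[t - 1, 0:6] * (1.0 - q_by_state)
        recurrers = survivors * p_rec
        rec[t] = recurrers.sum()
        for s in range(6):
            dest = post_recur.truncated(s)
            rec_band[t, 0] += recurrers[s] * dest[0:3].sum()
            rec_band[t, 1] += recurrers[s] * dest[3:6].sum()
            rec_band[t, 2] += recurrers[s] * dest[6]
        deaths[t] = occ[t, DEAD] - occ[t - 1, DEAD]

    ages = spec.start_age + np.arange(h + 1) * spec.cycle_length
    return Trace(
        occupancy=occ,
        ages=ages,
        recurrences=rec,
        recurrences_by_band=rec_band,
        deaths=deaths,
    )


def with_horizon(spec: ModelSpec, horizon: int) -> ModelSpec:
    return replace(spec, horizon=horizon)
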