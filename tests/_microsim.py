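"""Individual-level microsimulation oracle for the cohort Markov model.

Walks individual patients through the same within-cycle event order the
transition matrices encode (death, then recurrence among survivors with a
truncated-and-renormalized destination draw, then stay).  Written directly
against the event description, independently of the matrix construction,
so agreement between the two is an actual cross-check.
"""

import numpy as np

from strokecea.cohort_model import DEAD, N_STATES, adjust_annual_probability


def microsimulate(
    initial_p,
    spec,
    life_table,
    hrs,
    recurrence,
    post_recur,
    n_walkers,
    seed,
    record_cycles=None,
):
    """Return {cycle: occupancy fraction over the 8 states} for the
    requested cycles (all boundaries by default)."""
    rng = np.random.default_rng(seed)
    record_cycles = set(
        range(spec.horizon + 1) if record_cycles is None else record_cycles
    )

    init = np.asarray(initial_p, dtype=float)
    if init.shape == (7,):  # mRS distribution: mRS6 enters dead
        full = np.zeros(N_STATES)
        full[0:6] = init[0:6]
        full[DEAD] = init[6]
        init = full
    state = rng.choice(N_STATES, size=n_walkers, p=init / init.sum())

    trunc = np.vstack([post_recur.truncated(s) for s in range(6)])
    trunc_cdf = np.cumsum(trunc, axis=1)

    out = {}
    if 0 in record_cycles:
        out[0] = np.bincount(state, minlength=N_STATES) / n_walkers

    for t in range(1, spec.horizon + 1):
        age = spec.start_age + t * spec.cycle_length
        q = life_table.q(age)
        p_die = np.array(
            [adjust_annual_probability(q, hrs.by_state[s]) for s in range(6)]
        )
        p_rec = recurrence.prob(t)

        alive = state < 6
        u_death = rng.random(n_walkers)
        dies = alive & (u_death < p_die[np.minimum(state, 5)])
        u_rec = rng.random(n_walkers)
        recurs = alive & ~dies & (u_rec < p_rec)

        if recurs.any():
            u_dest = rng.random(recurs.sum())
            rows = trunc_cdf[state[recurs]]
            dest = (u_dest[:, None] > rows).sum(axis=1)
            dest = np.where(dest == 6, DEAD, dest)
            state[recurs] = dest
        state[dies] = DEAD

        if t in record_cycles:
            out[t] = np.bincount(state, minlength=N_STATES) / n_walkers
    return out
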