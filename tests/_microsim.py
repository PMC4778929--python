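"""Independent individual-level microsimulation oracle.

Re-implements the cohort model's stated semantics at the patient level with
random transitions, written directly from the state-transition description
and sharing no code with the cohort engine. Used to validate `run_cohort`.
"""

from __future__ import annotations

import numpy as np

from tkrcea.markov import ModelInputs


def microsimulate(inputs: ModelInputs, n_patients: int, seed: int = 0):
    """Simulate ``n_patients`` individual trajectories; returns mean QALYs,
    mean discounted cost, lifetime first-revision proportion, and Monte-Carlo
    SEs of the two means."""
    rng = np.random.default_rng(seed)
    n = n_patients
    INTACT, REV, POSTREV, DEAD = 0, 1, 2, 3

    state = np.full(n, INTACT)
    dead0 = rng.random(n) < inputs.operative_mortality
    state[dead0] = DEAD

    disc = 1.0 + inputs.discount_rate
    floor = inputs.utility_floor
    u_pri = float(np.asarray(inputs.utility_primary))
    u_later = (u_pri if inputs.utility_primary_later is None
               else float(np.asarray(inputs.utility_primary_later)))
    u_rev = float(np.asarray(inputs.utility_revision_year))
    u_post = float(np.asarray(inputs.utility_post_revision))
    p_rev = np.asarray(inputs.p_revision, dtype=float)
    r1 = float(np.asarray(inputs.p_rerevision_year1))
    r2 = float(np.asarray(inputs.p_rerevision_later))

    qalys = np.zeros(n)
    costs = np.zeros(n)
    ever_revised = np.zeros(n, dtype=bool)

    init = (inputs.prosthesis_price + inputs.theatre_cost
            + float(np.asarray(inputs.los_days)) * inputs.bed_day_cost)
    costs += init
    qalys += np.where(state == INTACT, max(u_pri, floor), 0.0)

    decline = 0.0
    for t in range(1, inputs.n_cycles):
        q = inputs.mortality[t - 1]
        alive = state != DEAD
        dies = alive & (rng.random(n) < q)
        state[dies] = DEAD

        was_intact = state == INTACT
        was_rev = state == REV
        was_post = state == POSTREV

        new_first = was_intact & (rng.random(n) < p_rev[t - 1])
        re_early = was_rev & (rng.random(n) < r1)
        re_late = was_post & (rng.random(n) < r2)

        state[was_rev & ~re_early] = POSTREV
        state[new_first | re_early | re_late] = REV
        ever_revised |= new_first

        decline += inputs.aging_kappa * (inputs.age_at_surgery + t) ** 2
        d = disc ** (-t)
        utils = np.array([max(u_later - decline, floor),
                          max(u_rev - decline, floor),
                          max(u_post - decline, floor), 0.0])
        qalys += d * utils[state]
        costs += d * inputs.revision_cost * (new_first | re_early | re_late)

    return {
        "qalys": qalys.mean(),
        "cost": costs.mean(),
        "proportion_revised": ever_revised.mean(),
        "qalys_se": qalys.std(ddof=1) / np.sqrt(n),
        "cost_se": costs.std(ddof=1) / np.sqrt(n),
    }
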