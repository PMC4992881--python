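"""Independent brute-force oracles used by the tests.

Everything here recomputes life-table quantities straight from the
individual records by explicit enumeration/propagation, deliberately
avoiding the package's own backward recursions and bisection solver.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
from scipy.optimize import brentq


def mean_lifespan(cohort) -> float:
    return float(np.mean([ind.lifespan for ind in cohort]))


def oracle_r(lm_x, lo=-1.0, hi=2.0) -> float:
    """Renewal-equation root via scipy's brentq (independent of the
    package's bisection)."""
    lm = np.asarray(lm_x, dtype=float)
    x1 = np.arange(1, len(lm) + 1)

    def f(r):
        return float(np.exp(-r * x1[lm > 0]) @ lm[lm > 0]) - 1.0

    while f(lo) < 0:
        lo *= 2
    while f(hi) > 0:
        hi *= 2
    return float(brentq(f, lo, hi, xtol=1e-14))


def brute_transitions(cohort):
    """(x, stage) -> dict of next state ('dead' or stage name) -> fraction."""
    nxt = defaultdict(list)
    for ind in cohort:
        for x, s in enumerate(ind.stages):
            after = ind.stages[x + 1] if x + 1 < ind.lifespan else "dead"
            nxt[(x, s)].append(after)
    return {
        key: {state: states.count(state) / len(states) for state in set(states)}
        for key, states in nxt.items()
    }


def brute_f(cohort):
    """age -> mean eggs per female alive at that age (0 where no female)."""
    eggs = defaultdict(float)
    females = defaultdict(int)
    for ind in cohort:
        for x, (s, e) in enumerate(zip(ind.stages, ind.eggs)):
            if s == "female":
                females[x] += 1
                eggs[x] += e
    return {x: (eggs[x] / females[x] if females[x] else 0.0) for x in females}


def _propagate(cohort, x0, j0):
    """Yield (age, {stage: mass}) for the expected-survival matrix s' that
    starts as 1 at (x0, j0) and follows the empirical transitions."""
    probs = brute_transitions(cohort)
    x_max = max(ind.death_age for ind in cohort)
    mass = {j0: 1.0}
    x = x0
    while mass and x <= x_max:
        yield x, dict(mass)
        new = defaultdict(float)
        for j, m in mass.items():
            for state, q in probs.get((x, j), {}).items():
                if state != "dead":
                    new[state] += m * q
        mass = {k: v for k, v in new.items() if v > 0}
        x += 1


def forward_life_expectancy(cohort, x0, j0) -> float:
    """e_xj as the explicit double sum over the propagated s' matrix."""
    return float(sum(sum(mass.values()) for _, mass in _propagate(cohort, x0, j0)))


def forward_reproductive_value(cohort, x0, j0, r) -> float:
    """v_xj = e^{r(x0+1)} sum_{i>=x0} e^{-r(i+1)} sum_y s'_iy f_iy."""
    f = brute_f(cohort)
    total = 0.0
    for i, mass in _propagate(cohort, x0, j0):
        fec = mass.get("female", 0.0) * f.get(i, 0.0)
        total += np.exp(-r * (i + 1)) * fec
    return float(np.exp(r * (x0 + 1)) * total)
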