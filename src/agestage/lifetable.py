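"""Age-stage, two-sex life table: schedules, e_xj, v_xj and r, lambda, R0, T.

The model follows the standard age-stage, two-sex framework for daily insect
census data.  With a cohort of ``n`` eggs followed until the last death at
age ``X_max``:

* ``s_xj = n_xj / n`` -- probability that a newly laid egg is alive and in
  stage j at age x (stages ordered egg, larva, pupa, female, male);
* ``l_x = sum_j s_xj`` -- age-specific survivorship;
* ``f_x4`` -- mean eggs per adult female alive at age x (only females lay);
* ``m_x`` -- mean eggs per individual alive at age x, so ``l_x m_x`` is the
  age-specific maternity and ``R0 = sum_x l_x m_x`` the net reproductive rate
  (exactly total eggs laid / n, both sexes and pre-adult deaths in the
  denominator);
* ``r`` -- the intrinsic rate of increase, the unique root of the discrete
  renewal equation ``sum_x exp(-r (x+1)) l_x m_x = 1``.  The ``x+1`` exponent
  is the fixed convention of the framework for 0-based ages (eggs laid during
  day x are counted as newborns from day x+1); changing it shifts r
  materially.
* ``lambda = exp(r)`` and mean generation time ``T = ln(R0)/r``.

Age-stage life expectancy ``e_xj`` and reproductive value ``v_xj`` are
computed by backward recursion over the empirical daily transition
probabilities (stay in stage / advance / die), pooled over all individuals
observed at each (age, stage) with no smoothing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    STAGES,
    STAGE_CODE,
    TraitSummary,
    read_life_history,
    summarize_traits,
    validate_cohort,
    CohortValidationError,
    TPOP_CONVENTION,
)

__all__ = [
    "AgeStageCounts",
    "Schedule",
    "TransitionModel",
    "DemographicParams",
    "LifeTable",
    "LifeTableResults",
    "age_stage_counts",
    "survival_rates",
    "build_schedule",
    "net_reproductive_rate",
    "solve_intrinsic_rate",
    "derived_rates",
    "transition_probabilities",
    "life_expectancy",
    "reproductive_value",
    "analyze",
]

N_STAGES = len(STAGES)
FEMALE = STAGE_CODE["female"]


class NoReproductionError(ValueError):
    """Raised when r is requested for a cohort with R0 = 0."""


@dataclass(frozen=True)
class Schedule:
    """Age-indexed survival and fecundity schedules (index = age in days)."""

    l_x: np.ndarray
    f_x4: np.ndarray
    m_x: np.ndarray
    lm_x: np.ndarray

    @property
    def ages(self) -> np.ndarray:
        return np.arange(len(self.l_x))

    @property
    def x_max(self) -> int:
        return len(self.l_x) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "l_x": self.l_x,
                "f_x4": self.f_x4,
                "m_x": self.m_x,
                "lm_x": self.lm_x,
            }
        )


@dataclass(frozen=True)
class TransitionModel:
    """Empirical daily transitions between (age, stage) cells.

    ``transition[x, j, k]`` is the probability that an individual observed at
    age x in stage j is alive in stage k at age x+1; the death probability is
    the complement of the row sum.  ``at_risk[x, j]`` holds the pooled counts
    (= n_xj).  The model is "closed": at the terminal age every lineage dies.
    """

    transition: np.ndarray  # (X_max+1, 5, 5)
    at_risk: np.ndarray  # (X_max+1, 5) integer counts

    @property
    def x_max(self) -> int:
        return self.transition.shape[0] - 1

    @property
    def observed(self) -> np.ndarray:
        return self.at_risk > 0

    def p_die(self, x: int, j: int) -> float:
        return 1.0 - float(self.transition[x, j].sum())

    def p_stay(self, x: int, j: int) -> float:
        return float(self.transition[x, j, j])

    def p_grow(self, x: int, j: int) -> float:
        return float(self.transition[x, j].sum() - self.transition[x, j, j])

    def validate(self) -> None:
        rows = self.transition.sum(axis=2)
        if (rows > 1.0 + 1e-9).any():
            raise ValueError("transition rows exceed probability 1")
        if rows[-1][self.observed[-1]].any():
            raise ValueError("model not closed: survival beyond the terminal age")


@dataclass(frozen=True)
class DemographicParams:
    """Point estimates of the population parameters.

    ``r`` in d^-1, ``lambda_`` (= exp(r)) per day, ``R0`` in offspring per
    newborn individual, ``T`` in days.  When the cohort never reproduces,
    ``R0 = 0`` and r, lambda and T are NaN.
    """

    r: float
    lambda_: float
    R0: float
    T: float
    n: int
    x_max: int

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "lambda": self.lambda_,
            "R0": self.R0,
            "T": self.T,
            "n": self.n,
            "X_max": self.x_max,
        }


# ---------------------------------------------------------------------------
# elemental operations


def _stage_codes(cohort: Cohort) -> list[np.ndarray]:
    return [
        np.fromiter((STAGE_CODE[s] for s in ind.stages), dtype=np.intp, count=ind.lifespan)
        for ind in cohort.individuals
    ]


def age_stage_counts(cohort: Cohort) -> np.ndarray:
    """n_xj: individuals observed in stage j at age x, shape (X_max+1, 5)."""
    x_max = cohort.x_max
    counts = np.zeros((x_max + 1, N_STAGES), dtype=np.int64)
    for codes in _stage_codes(cohort):
        np.add.at(counts, (np.arange(len(codes)), codes), 1)
    return counts


def survival_rates(counts: np.ndarray, n: int) -> np.ndarray:
    """s_xj = n_xj / n (n = initial number of eggs)."""
    if n <= 0:
        raise ValueError("cohort size n must be positive")
    return counts.astype(float) / float(n)


def _eggs_by_age(cohort: Cohort) -> np.ndarray:
    eggs = np.zeros(cohort.x_max + 1)
    for ind in cohort.individuals:
        eggs[: ind.lifespan] += np.asarray(ind.eggs, dtype=float)
    return eggs


def build_schedule(cohort: Cohort, s_xj: np.ndarray) -> Schedule:
    """l_x, f_x4, m_x and l_x*m_x from the survival matrix and egg counts.

    m_x = (total eggs at age x) / (individuals alive at age x); ages where no
    one is alive (none exist below X_max) or no female is alive yield 0, not
    NaN.
    """
    n = cohort.n
    eggs = _eggs_by_age(cohort)
    l_x = s_xj.sum(axis=1)
    females_alive = s_xj[:, FEMALE] * n
    alive = l_x * n
    f_x4 = np.divide(eggs, females_alive, out=np.zeros_like(eggs), where=females_alive > 0)
    m_x = np.divide(eggs, alive, out=np.zeros_like(eggs), where=alive > 0)
    return Schedule(l_x=l_x, f_x4=f_x4, m_x=m_x, lm_x=l_x * m_x)


def net_reproductive_rate(schedule: Schedule) -> float:
    """R0 = sum_x l_x m_x (identically total eggs laid / n)."""
    return float(schedule.lm_x.sum())


def renewal_residual(r: float, lm_x: np.ndarray) -> float:
    """sum_x exp(-r (x+1)) l_x m_x - 1; decreasing in r.

    Only ages with positive maternity contribute, which keeps the residual
    finite-or-inf (never NaN) even when the trial r makes exp overflow.
    """
    pos = lm_x > 0
    x1 = np.nonzero(pos)[0] + 1.0
    with np.errstate(over="ignore"):
        return float(np.exp(-r * x1) @ lm_x[pos]) - 1.0


def solve_intrinsic_rate(schedule: Schedule, tol: float = 1e-12) -> float:
    """Root of the renewal equation by deterministic bracketing bisection.

    Starts from the bracket [-1, 2] d^-1 and doubles the endpoints outward if
    the root lies outside; bisects to machine precision and checks the final
    residual against ``tol``.
    """
    lm = schedule.lm_x
    if lm.sum() <= 0:
        raise NoReproductionError("no reproduction, r undefined")
    lo, hi = -1.0, 2.0
    for _ in range(60):
        if renewal_residual(lo, lm) > 0:
            break
        lo *= 2.0
    else:
        raise ValueError("could not bracket r from below")
    for _ in range(60):
        if renewal_residual(hi, lm) < 0:
            break
        hi *= 2.0
    else:
        raise ValueError("could not bracket r from above")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if renewal_residual(mid, lm) > 0:
            lo = mid
        else:
            hi = mid
    r = 0.5 * (lo + hi)
    if abs(renewal_residual(r, lm)) > tol:
        raise ValueError(f"renewal residual exceeds tolerance {tol}")
    return r


def derived_rates(
    r: float, R0: float, schedule: Optional[Schedule] = None
) -> tuple[float, float]:
    """lambda = exp(r); T = ln(R0)/r, with the r -> 0 limit
    T = sum (x+1) l_x m_x / R0 (the cohort generation time) as fallback."""
    lam = math.exp(r)
    if R0 <= 0:
        return lam, float("nan")
    if abs(r) > 1e-10:
        T = math.log(R0) / r
    else:
        if schedule is None:
            raise ValueError("schedule required for the r=0 generation-time limit")
        x1 = np.arange(1, len(schedule.lm_x) + 1, dtype=float)
        T = float((x1 @ schedule.lm_x) / R0)
    return lam, T


def transition_probabilities(cohort: Cohort) -> TransitionModel:
    """Empirical per-(age, stage) daily transition fractions.

    For each (x, j), the individuals observed there either appear at
    (x+1, same stage), at (x+1, a later stage), or are dead at x+1; the three
    fractions sum to one.  All individuals are pooled; no smoothing.
    """
    x_max = cohort.x_max
    moves = np.zeros((x_max + 1, N_STAGES, N_STAGES))
    at_risk = np.zeros((x_max + 1, N_STAGES), dtype=np.int64)
    for codes in _stage_codes(cohort):
        ages = np.arange(len(codes))
        np.add.at(at_risk, (ages, codes), 1)
        if len(codes) > 1:
            np.add.at(moves, (ages[:-1], codes[:-1], codes[1:]), 1)
    with np.errstate(invalid="ignore"):
        transition = moves / at_risk[:, :, None]
    transition[~np.isfinite(transition)] = 0.0
    model = TransitionModel(transition=transition, at_risk=at_risk)
    model.validate()
    return model


def life_expectancy(model: TransitionModel) -> np.ndarray:
    """e_xj by backward recursion: e_xj = 1 + sum_k P[x,j,k] e_{x+1,k}.

    Counts the current day, so e >= 1 wherever the cell is observed and
    e = 1 at the terminal age of a lineage.  Unobserved cells are NaN.
    """
    model.validate()
    x_max = model.x_max
    e = np.full((x_max + 1, N_STAGES), np.nan)
    nxt = np.zeros(N_STAGES)
    for x in range(x_max, -1, -1):
        row = 1.0 + model.transition[x] @ nxt
        e[x] = np.where(model.observed[x], row, np.nan)
        nxt = np.nan_to_num(e[x])
    return e


def reproductive_value(
    model: TransitionModel, schedule: Schedule, r: float
) -> np.ndarray:
    """v_xj by backward recursion:
    v_xj = f_xj + exp(-r) sum_k P[x,j,k] v_{x+1,k}.

    ``f_xj`` is the mean fecundity of stage j at age x (nonzero only for the
    adult female stage).  v is the expected future offspring of an individual
    at (x, j), discounted at rate r; it is 0 wherever no fecund female-day is
    reachable (e.g. the male column).
    """
    model.validate()
    x_max = model.x_max
    f = np.zeros((x_max + 1, N_STAGES))
    f[:, FEMALE] = schedule.f_x4[: x_max + 1]
    disc = math.exp(-r)
    v = np.full((x_max + 1, N_STAGES), np.nan)
    nxt = np.zeros(N_STAGES)
    for x in range(x_max, -1, -1):
        row = f[x] + disc * (model.transition[x] @ nxt)
        v[x] = np.where(model.observed[x], row, np.nan)
        nxt = np.nan_to_num(v[x])
    return v


# ---------------------------------------------------------------------------
# model / results objects


class LifeTable:
    """Age-stage, two-sex life-table model for one cohort.

    Parameters
    ----------
    cohort
        A validated :class:`~agestage.cohort.Cohort`.
    validate
        Re-run the cohort validator on construction (default True).

    Examples
    --------
    >>> lt = LifeTable.from_csv("life_history.csv")
    >>> res = lt.fit()
    >>> res.params.R0, res.params.r
    """

    def __init__(self, cohort: Cohort, validate: bool = True):
        if validate:
            report = validate_cohort(cohort)
            if not report.ok:
                raise CohortValidationError(str(report))
        self.cohort = cohort

    @classmethod
    def from_csv(cls, path: str | Path, label: Optional[str] = None) -> "LifeTable":
        return cls(read_life_history(path, label=label), validate=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "LifeTable":
        report_df = df.copy()
        report_df["individual_id"] = report_df["individual_id"].astype(str)
        from .cohort import validate_frame

        report = validate_frame(report_df)
        if not report.ok:
            raise CohortValidationError(str(report))
        return cls(Cohort.from_frame(report_df, label=label), validate=False)

    def fit(
        self, tol: float = 1e-12, require_reproduction: bool = True
    ) -> "LifeTableResults":
        """Compute the full life-table bundle in one deterministic pass.

        With ``require_reproduction`` (default) a cohort that never lays any
        egg raises :class:`NoReproductionError`; otherwise r, lambda, T and
        v_xj are left undefined (NaN / None).
        """
        cohort = self.cohort
        counts = age_stage_counts(cohort)
        s_xj = survival_rates(counts, cohort.n)
        schedule = build_schedule(cohort, s_xj)
        R0 = net_reproductive_rate(schedule)
        model = transition_probabilities(cohort)
        e_xj = life_expectancy(model)
        if R0 > 0:
            r = solve_intrinsic_rate(schedule, tol=tol)
            lam, T = derived_rates(r, R0, schedule)
            v_xj = reproductive_value(model, schedule, r)
        elif require_reproduction:
            raise NoReproductionError("no reproduction, r undefined")
        else:
            r = lam = T = float("nan")
            v_xj = None
        params = DemographicParams(
            r=r, lambda_=lam, R0=R0, T=T, n=cohort.n, x_max=cohort.x_max
        )
        return LifeTableResults(
            model=self,
            counts=counts,
            survival=s_xj,
            schedule=schedule,
            transitions=model,
            e_xj=e_xj,
            v_xj=v_xj,
            params=params,
            traits=summarize_traits(cohort),
        )


@dataclass
class LifeTableResults:
    """Fitted life table: matrices, schedules and demographic parameters."""

    model: LifeTable
    counts: np.ndarray
    survival: np.ndarray
    schedule: Schedule
    transitions: TransitionModel
    e_xj: np.ndarray
    v_xj: Optional[np.ndarray]
    params: DemographicParams
    traits: TraitSummary

    @property
    def cohort(self) -> Cohort:
        return self.model.cohort

    # -- presentation ----------------------------------------------------
    def _stage_frame(self, mat: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(mat, columns=list(STAGES))
        df.insert(0, "age", np.arange(len(df)))
        return df

    @property
    def survival_frame(self) -> pd.DataFrame:
        return self._stage_frame(self.survival)

    @property
    def life_expectancy_frame(self) -> pd.DataFrame:
        return self._stage_frame(self.e_xj)

    @property
    def reproductive_value_frame(self) -> Optional[pd.DataFrame]:
        return None if self.v_xj is None else self._stage_frame(self.v_xj)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Age-stage two-sex life table",
            "============================",
            f"cohort: {self.cohort.label or '<unnamed>'}   n = {p.n}   X_max = {p.x_max} d",
            f"females: {len(self.cohort.females)}   males: {len(self.cohort.males)}   "
            f"pre-adult deaths: {sum(1 for i in self.cohort if i.died_pre_adult)}",
            "",
            "Population parameters",
            "---------------------",
            f"r      {p.r: .6f}  d^-1   (intrinsic rate of increase)",
            f"lambda {p.lambda_: .6f}  d^-1   (finite rate of increase)",
            f"R0     {p.R0: .4f}  offspring/individual (net reproductive rate)",
            f"T      {p.T: .2f}  d      (mean generation time)",
            "",
            "Traits (mean +/- SE [n])",
            "------------------------",
        ]
        for name, stat in self.traits.traits.items():
            lines.append(f"{name:18s} {stat.mean:10.3f} +/- {stat.se:8.3f}  [{stat.n}]")
        return "\n".join(lines)

    # -- downstream analyses ---------------------------------------------
    def bootstrap(self, B: int = 1000, seed: int = 0, alpha: float = 0.05,
                  statistics: Optional[Sequence[str]] = None):
        from .bootstrap import BootstrapConfig, bootstrap_estimates

        cfg = BootstrapConfig(B=B, seed=seed, alpha=alpha)
        return bootstrap_estimates(self.cohort, cfg, statistics=statistics)

    def project(self, initial_eggs: float = 10.0, horizon: int = 600):
        from .projection import ProjectionConfig, project

        cfg = ProjectionConfig(initial_eggs=initial_eggs, horizon=horizon)
        return project(self.survival, self.schedule.lm_x, cfg)

    # -- export ----------------------------------------------------------
    def save(self, outdir: str | Path, seed: Optional[int] = None) -> list[Path]:
        """Write sxj.tsv, exj.tsv, vxj.tsv, schedule.tsv, traits.tsv and
        params.json with metadata headers; returns the written paths."""
        from .reporting import write_tsv, metadata

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = metadata(seed=seed, cohort=self.cohort.label, n=self.params.n)
        written = []
        for name, frame in (
            ("sxj.tsv", self.survival_frame),
            ("exj.tsv", self.life_expectancy_frame),
            ("vxj.tsv", self.reproductive_value_frame),
            ("schedule.tsv", self.schedule.to_frame()),
            ("traits.tsv", self.traits.to_frame()),
        ):
            if frame is None:
                continue
            path = outdir / name
            extra = {"tpop_convention": TPOP_CONVENTION} if name == "traits.tsv" else {}
            write_tsv(path, frame, {**meta, **extra})
            written.append(path)
        params_path = outdir / "params.json"
        payload = {**self.params.as_dict(), "metadata": meta}
        params_path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
        written.append(params_path)
        return written


def analyze(cohort: Cohort, tol: float = 1e-12) -> LifeTableResults:
    """One-call pipeline: validate, fit and return the full bundle."""
    return LifeTable(cohort).fit(tol=tol)
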