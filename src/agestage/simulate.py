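"""Synthetic cohorts with known ground truth.

The generator emulates the constant-temperature rearing design behind the
red palm weevil life tables: cohorts of eggs followed daily through egg,
larva and pupa to adulthood, a roughly 1:1 sex ratio, and age-structured
daily fecundity.  Six presets (21C .. 36C) are calibrated to the published
trait means at each viable temperature (stage durations, APOP, oviposition
days, total fecundity); development fails at 15 and 18 degrees, so those
labels are rejected.  Dispersion and pre-adult survival are module defaults,
documented in the methods note, not claims about the unpublished raw
cohorts.

Generative model per individual (all distributions discretized to whole
days, durations at least 1 d):

1. egg, larva and pupa durations ~ independent discretized truncated
   normals; each stage is completed with probability q_stage, otherwise the
   individual dies on a uniformly chosen day of that stage;
2. survivors become female with probability ``sex_ratio``; adult lifespan is
   a discretized normal per sex;
3. a female draws an adult pre-oviposition period (APOP), an oviposition
   window length and a total fecundity; her adult lifespan is extended, if
   needed, to cover the oviposition window, and the total eggs are spread
   over the window multinomially under a gamma-shaped (or uniform) daily
   envelope.

Because every ingredient has finite discrete support, the exact expected
schedules (l_x, m_x and the stage occupancies s_xj) implied by a config are
computable by convolution, with no sampling: :func:`analytic_schedule` and
:func:`analytic_params` provide the ground truth for parameter-recovery
tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .cohort import Cohort, IndividualRecord, PREADULT_STAGES
from .lifetable import DemographicParams, Schedule, derived_rates, solve_intrinsic_rate

__all__ = [
    "DiscreteDist",
    "discretized_normal",
    "discretized_gamma",
    "point_mass",
    "FecundityModel",
    "GeneratorConfig",
    "AnalyticSchedule",
    "PRESET_LABELS",
    "preset",
    "generate_cohort",
    "analytic_schedule",
    "analytic_params",
]


# ---------------------------------------------------------------------------
# discrete distributions


@dataclass(frozen=True)
class DiscreteDist:
    """A finite discrete distribution on non-negative integers."""

    support: np.ndarray
    pmf: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.support) != len(self.pmf) or len(self.support) == 0:
            raise ValueError("support and pmf must be non-empty and equal length")
        if (self.pmf < 0).any() or abs(self.pmf.sum() - 1.0) > 1e-9:
            raise ValueError("pmf must be non-negative and sum to 1")

    @property
    def max(self) -> int:
        return int(self.support[-1])

    def mean(self) -> float:
        return float(self.support @ self.pmf)

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        return rng.choice(self.support, size=size, p=self.pmf)

    def dense(self, length: Optional[int] = None) -> np.ndarray:
        """pmf as a dense vector indexed by value 0..length-1."""
        length = self.max + 1 if length is None else length
        out = np.zeros(length)
        out[self.support] = self.pmf
        return out

    def survival(self) -> np.ndarray:
        """S[k] = P(X >= k+1) for k = 0..max-1 (days alive given lifespan X)."""
        dense = self.dense()
        return np.cumsum(dense[::-1])[::-1][1:]

    def to_dict(self) -> dict:
        if self.meta:
            return dict(self.meta)
        return {
            "kind": "explicit",
            "support": self.support.tolist(),
            "pmf": self.pmf.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteDist":
        kind = d["kind"]
        if kind == "normal":
            return discretized_normal(d["mean"], d["sd"], minimum=d["minimum"])
        if kind == "gamma":
            return discretized_gamma(d["mean"], d["sd"])
        if kind == "point":
            return point_mass(d["value"])
        if kind == "explicit":
            return cls(np.asarray(d["support"], dtype=int), np.asarray(d["pmf"], dtype=float))
        raise ValueError(f"unknown distribution kind {kind!r}")


def point_mass(value: int) -> DiscreteDist:
    return DiscreteDist(
        support=np.array([int(value)]),
        pmf=np.array([1.0]),
        meta={"kind": "point", "value": int(value)},
    )


def discretized_normal(mean: float, sd: float, minimum: int = 1, width: float = 4.0) -> DiscreteDist:
    """Normal(mean, sd) truncated to [minimum, mean + width*sd] and binned to
    whole days; sd = 0 collapses to a point mass."""
    if sd <= 0:
        return point_mass(max(minimum, round(mean)))
    top = max(minimum, math.ceil(mean + width * sd))
    support = np.arange(minimum, top + 1)
    edges = np.concatenate(([-np.inf], support[:-1] + 0.5, [np.inf]))
    cdf = sps.norm.cdf(edges, loc=mean, scale=sd)
    pmf = np.diff(cdf)
    pmf = pmf / pmf.sum()
    return DiscreteDist(
        support=support,
        pmf=pmf,
        meta={"kind": "normal", "mean": float(mean), "sd": float(sd), "minimum": int(minimum)},
    )


def discretized_gamma(mean: float, sd: float) -> DiscreteDist:
    """Gamma with the given mean and sd, binned to whole counts (support from
    0); sd = 0 collapses to a point mass."""
    if sd <= 0:
        return point_mass(max(0, round(mean)))
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    top = int(math.ceil(sps.gamma.ppf(1.0 - 1e-9, shape, scale=scale)))
    support = np.arange(0, top + 1)
    edges = np.concatenate(([-np.inf], support[:-1] + 0.5, [np.inf]))
    cdf = sps.gamma.cdf(edges, shape, scale=scale)
    pmf = np.diff(cdf)
    pmf = pmf / pmf.sum()
    return DiscreteDist(
        support=support,
        pmf=pmf,
        meta={"kind": "gamma", "mean": float(mean), "sd": float(sd)},
    )


# ---------------------------------------------------------------------------
# generator configuration


def envelope_weights(n_days: int, kind: str = "gamma", shape: float = 2.0) -> np.ndarray:
    """Daily egg-laying envelope over an oviposition window: gamma-shaped
    (early peak, long tail) or uniform; normalised to sum to 1."""
    if n_days < 1:
        raise ValueError("oviposition window must span at least 1 day")
    if kind == "uniform":
        return np.full(n_days, 1.0 / n_days)
    if kind != "gamma":
        raise ValueError("envelope kind must be 'gamma' or 'uniform'")
    t = np.arange(n_days) + 0.5
    scale = max(n_days / 4.0, 1.0)
    w = t ** (shape - 1.0) * np.exp(-t / scale)
    return w / w.sum()


@dataclass(frozen=True)
class FecundityModel:
    """APOP, oviposition-window length and total lifetime fecundity, plus the
    shape of the daily laying envelope."""

    total: DiscreteDist
    apop: DiscreteDist
    oviposition_days: DiscreteDist
    envelope: str = "gamma"
    envelope_shape: float = 2.0

    def to_dict(self) -> dict:
        return {
            "total": self.total.to_dict(),
            "apop": self.apop.to_dict(),
            "oviposition_days": self.oviposition_days.to_dict(),
            "envelope": self.envelope,
            "envelope_shape": self.envelope_shape,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FecundityModel":
        return cls(
            total=DiscreteDist.from_dict(d["total"]),
            apop=DiscreteDist.from_dict(d["apop"]),
            oviposition_days=DiscreteDist.from_dict(d["oviposition_days"]),
            envelope=d.get("envelope", "gamma"),
            envelope_shape=d.get("envelope_shape", 2.0),
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Distributional ground truth for one synthetic treatment."""

    label: str
    stage_durations: dict  # stage -> DiscreteDist for egg, larva, pupa
    stage_survival: dict  # stage -> completion probability in [0, 1]
    female_longevity: DiscreteDist
    male_longevity: DiscreteDist
    fecundity: FecundityModel
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        for s in PREADULT_STAGES:
            if s not in self.stage_durations:
                raise ValueError(f"missing duration distribution for stage {s!r}")
            q = self.stage_survival.get(s)
            if q is None or not 0.0 <= q <= 1.0:
                raise ValueError(f"stage survival for {s!r} must lie in [0, 1]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")

    @property
    def preadult_survival(self) -> float:
        out = 1.0
        for s in PREADULT_STAGES:
            out *= self.stage_survival[s]
        return out

    def expected_R0(self) -> float:
        """Closed-form net reproductive rate implied by the config:
        (probability female) x (survival to adult) x (mean fecundity)."""
        return self.sex_ratio * self.preadult_survival * self.fecundity.total.mean()

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "stage_durations": {s: d.to_dict() for s, d in self.stage_durations.items()},
            "stage_survival": dict(self.stage_survival),
            "female_longevity": self.female_longevity.to_dict(),
            "male_longevity": self.male_longevity.to_dict(),
            "fecundity": self.fecundity.to_dict(),
            "sex_ratio": self.sex_ratio,
        }

    def to_json(self, **extra) -> str:
        return json.dumps({**self.to_dict(), **extra}, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(
            label=d["label"],
            stage_durations={s: DiscreteDist.from_dict(v) for s, v in d["stage_durations"].items()},
            stage_survival={s: float(v) for s, v in d["stage_survival"].items()},
            female_longevity=DiscreteDist.from_dict(d["female_longevity"]),
            male_longevity=DiscreteDist.from_dict(d["male_longevity"]),
            fecundity=FecundityModel.from_dict(d["fecundity"]),
            sex_ratio=float(d["sex_ratio"]),
        )


# ---------------------------------------------------------------------------
# presets calibrated to the published trait means


PRESET_LABELS = ("21C", "24C", "27C", "30C", "33C", "36C")
NONVIABLE_LABELS = ("15C", "18C")

# published trait means and their SEs per temperature:
# (egg, larva, pupa, female adult, male adult, APOP, oviposition days, fecundity)
_TABLE_MEANS = {
    "21C": {"egg": 6.6, "larva": 215.4, "pupa": 16.1, "female": 144.5, "male": 87.1,
            "apop": 10.1, "ovidays": 53.6, "fecundity": 75.2},
    "24C": {"egg": 4.4, "larva": 197.7, "pupa": 19.3, "female": 112.0, "male": 158.0,
            "apop": 8.2, "ovidays": 59.9, "fecundity": 97.0},
    "27C": {"egg": 3.3, "larva": 144.1, "pupa": 12.3, "female": 94.7, "male": 132.2,
            "apop": 4.7, "ovidays": 56.2, "fecundity": 125.0},
    "30C": {"egg": 2.7, "larva": 120.2, "pupa": 11.9, "female": 99.4, "male": 89.5,
            "apop": 7.0, "ovidays": 48.0, "fecundity": 124.1},
    "33C": {"egg": 2.3, "larva": 120.1, "pupa": 10.7, "female": 69.0, "male": 56.3,
            "apop": 6.1, "ovidays": 31.8, "fecundity": 108.1},
    "36C": {"egg": 2.2, "larva": 122.7, "pupa": 8.8, "female": 62.2, "male": 45.9,
            "apop": 4.8, "ovidays": 23.6, "fecundity": 42.1},
}
_TABLE_SES = {
    "21C": {"egg": 0.1, "larva": 5.6, "pupa": 0.8, "female": 10.8, "male": 13.8,
            "apop": 1.0, "ovidays": 4.1, "fecundity": 7.9},
    "24C": {"egg": 0.1, "larva": 9.8, "pupa": 0.8, "female": 18.4, "male": 11.7,
            "apop": 1.2, "ovidays": 11.4, "fecundity": 21.1},
    "27C": {"egg": 0.1, "larva": 8.1, "pupa": 0.3, "female": 10.1, "male": 15.9,
            "apop": 0.5, "ovidays": 6.3, "fecundity": 15.4},
    "30C": {"egg": 0.1, "larva": 3.5, "pupa": 0.3, "female": 12.6, "male": 9.6,
            "apop": 1.0, "ovidays": 5.7, "fecundity": 17.9},
    "33C": {"egg": 0.1, "larva": 6.3, "pupa": 0.4, "female": 10.3, "male": 7.0,
            "apop": 0.5, "ovidays": 6.9, "fecundity": 25.9},
    "36C": {"egg": 0.1, "larva": 5.8, "pupa": 0.3, "female": 14.1, "male": 12.2,
            "apop": 0.9, "ovidays": 3.2, "fecundity": 10.3},
}

# reported net reproductive rates, used only to set the overall pre-adult
# survival level (q_total = 2 R0 / fecundity with a 1:1 sex ratio) so that the
# synthetic treatments sit at a realistic reproductive scale
_TABLE_R0 = {"21C": 4.51, "24C": 8.41, "27C": 16.67, "30C": 9.93, "33C": 6.49, "36C": 1.69}

# egg-stage (hatch) survival levels: highest at 27C, lowest at the thermal
# extremes, following the qualitative ordering of the reported survival curves
_EGG_SURVIVAL = {"21C": 0.653, "24C": 0.70, "27C": 0.853, "30C": 0.78, "33C": 0.50, "36C": 0.58}
_PUPA_SURVIVAL = 0.90

# effective per-trait sample sizes used to convert the published SEs of means
# into individual-level SDs (SE * sqrt(n)); immature stages were followed from
# ~150 eggs per treatment, adult/reproductive traits rest on far fewer females
_N_IMMATURE = 120
_N_ADULT = 30
_SD_FLOOR = 0.5


def _sd(se: float, n: int) -> float:
    return max(se * math.sqrt(n), _SD_FLOOR)


def preset(temperature_label: str) -> GeneratorConfig:
    """Generator config for one of the six viable temperature treatments."""
    if temperature_label in NONVIABLE_LABELS:
        raise ValueError(
            f"{temperature_label}: development and reproduction fail at this "
            f"temperature; viable presets are {list(PRESET_LABELS)}"
        )
    if temperature_label not in PRESET_LABELS:
        raise ValueError(
            f"unknown preset {temperature_label!r}; valid labels are {list(PRESET_LABELS)}"
        )
    means = _TABLE_MEANS[temperature_label]
    ses = _TABLE_SES[temperature_label]
    q_total = 2.0 * _TABLE_R0[temperature_label] / means["fecundity"]
    q_egg = _EGG_SURVIVAL[temperature_label]
    q_larva = q_total / (q_egg * _PUPA_SURVIVAL)
    durations = {
        s: discretized_normal(means[s], _sd(ses[s], _N_IMMATURE), minimum=1)
        for s in PREADULT_STAGES
    }
    return GeneratorConfig(
        label=temperature_label,
        stage_durations=durations,
        stage_survival={"egg": q_egg, "larva": q_larva, "pupa": _PUPA_SURVIVAL},
        female_longevity=discretized_normal(means["female"], _sd(ses["female"], _N_ADULT), minimum=1),
        male_longevity=discretized_normal(means["male"], _sd(ses["male"], _N_ADULT), minimum=1),
        fecundity=FecundityModel(
            total=discretized_gamma(means["fecundity"], _sd(ses["fecundity"], _N_ADULT)),
            apop=discretized_normal(means["apop"], _sd(ses["apop"], _N_ADULT), minimum=0),
            oviposition_days=discretized_normal(means["ovidays"], _sd(ses["ovidays"], _N_ADULT), minimum=1),
        ),
        sex_ratio=0.5,
    )


# ---------------------------------------------------------------------------
# sampling


def generate_cohort(
    config: GeneratorConfig, n: int = 150, seed: int = 0
) -> Cohort:
    """Sample n individual life histories from the config; reproducible by
    seed and always valid under the cohort validator."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = np.random.default_rng(seed)
    fec = config.fecundity
    individuals = []
    for i in range(n):
        ident = f"{config.label or 'IND'}-{i + 1:04d}"
        stages: list[str] = []
        alive = True
        for s in PREADULT_STAGES:
            d = int(config.stage_durations[s].sample(rng))
            if rng.random() < config.stage_survival[s]:
                stages.extend([s] * d)
            else:
                last = int(rng.integers(0, d))  # last-alive day offset in stage
                stages.extend([s] * (last + 1))
                alive = False
                break
        eggs = None
        if alive:
            emergence = len(stages)
            if rng.random() < config.sex_ratio:
                ell = int(config.female_longevity.sample(rng))
                apop = int(fec.apop.sample(rng))
                window = int(fec.oviposition_days.sample(rng))
                ell = max(ell, apop + window)  # oviposition completes before death
                total = int(fec.total.sample(rng))
                stages.extend(["female"] * ell)
                eggs = np.zeros(len(stages), dtype=int)
                w = envelope_weights(window, fec.envelope, fec.envelope_shape)
                eggs[emergence + apop : emergence + apop + window] = rng.multinomial(total, w)
            else:
                stages.extend(["male"] * int(config.male_longevity.sample(rng)))
        if eggs is None:
            eggs = np.zeros(len(stages), dtype=int)
        individuals.append(
            IndividualRecord(
                individual_id=ident,
                stages=tuple(stages),
                eggs=tuple(int(e) for e in eggs),
            )
        )
    return Cohort(individuals=tuple(individuals), label=config.label)


# ---------------------------------------------------------------------------
# exact expected schedules (no sampling)


@dataclass(frozen=True)
class AnalyticSchedule:
    """Exact l_x, m_x and stage occupancies implied by a GeneratorConfig."""

    s_xj: np.ndarray  # expected occupancy per age x stage (egg..male)
    l_x: np.ndarray
    m_x: np.ndarray
    lm_x: np.ndarray

    @property
    def x_max(self) -> int:
        return len(self.l_x) - 1

    def to_schedule(self) -> Schedule:
        occ_female = self.s_xj[:, 3]
        f_x4 = np.divide(
            self.lm_x, occ_female, out=np.zeros_like(self.lm_x), where=occ_female > 0
        )
        return Schedule(l_x=self.l_x, f_x4=f_x4, m_x=self.m_x, lm_x=self.lm_x)


def _stage_occupancy_kernel(dist: DiscreteDist, q: float) -> np.ndarray:
    """psi[k] = P(occupying the stage k days after entry), mixing completion
    (prob q, present for the full sampled duration) with in-stage death
    (uniform last-alive day)."""
    psi = np.zeros(dist.max)
    for d, p in zip(dist.support, dist.pmf):
        k = np.arange(d)
        psi[:d] += p * (q + (1.0 - q) * (d - k) / d)
    return psi


def analytic_schedule(config: GeneratorConfig) -> AnalyticSchedule:
    """Exact expected schedules by convolving the config's distributions.

    All distributions have finite support, so every sum is finite and the
    result is exact to floating point; nothing is sampled.
    """
    fec = config.fecundity
    entry = np.array([1.0])  # pmf of entry time into the current stage
    occupancies = []
    for s in PREADULT_STAGES:
        dist = config.stage_durations[s]
        q = config.stage_survival[s]
        occupancies.append(np.convolve(entry, _stage_occupancy_kernel(dist, q)))
        entry = q * np.convolve(entry, dist.dense())
    h_adult = entry  # mass = pre-adult survival

    # female adult lifespan: max(longevity, APOP + oviposition window)
    po = np.convolve(fec.apop.dense(), fec.oviposition_days.dense())
    lf = config.female_longevity.dense()
    width = max(len(po), len(lf))
    cdf_max = np.cumsum(np.pad(po, (0, width - len(po)))) * np.cumsum(
        np.pad(lf, (0, width - len(lf)))
    )
    pmf_eff = np.diff(np.concatenate(([0.0], cdf_max)))
    s_female_alive = np.cumsum(pmf_eff[::-1])[::-1][1:]  # P(alive k days after emergence)
    s_male_alive = config.male_longevity.survival()

    phi = config.sex_ratio
    occ_female = phi * np.convolve(h_adult, s_female_alive)
    occ_male = (1.0 - phi) * np.convolve(h_adult, s_male_alive)
    occupancies.extend([occ_female, occ_male])

    # expected eggs per day since emergence: APOP shift * mixture of
    # envelopes over the window-length distribution, scaled by mean fecundity
    owidth = fec.oviposition_days.max
    inner = np.zeros(owidth)
    for o, p in zip(fec.oviposition_days.support, fec.oviposition_days.pmf):
        inner[:o] += p * envelope_weights(int(o), fec.envelope, fec.envelope_shape)
    eggs_since_emergence = fec.total.mean() * np.convolve(fec.apop.dense(), inner)
    b = phi * np.convolve(h_adult, eggs_since_emergence)  # eggs at age x per newborn

    width = max(max(len(o) for o in occupancies), len(b))
    s_xj = np.zeros((width, 5))
    for j, occ in enumerate(occupancies):
        s_xj[: len(occ), j] = occ
    b = np.pad(b, (0, width - len(b)))
    l_x = s_xj.sum(axis=1)
    last = int(np.nonzero(l_x > 0)[0][-1])
    s_xj, l_x, b = s_xj[: last + 1], l_x[: last + 1], b[: last + 1]
    m_x = np.divide(b, l_x, out=np.zeros_like(b), where=l_x > 0)
    return AnalyticSchedule(s_xj=s_xj, l_x=l_x, m_x=m_x, lm_x=b)


def analytic_params(config: GeneratorConfig, tol: float = 1e-12) -> DemographicParams:
    """Ground-truth r, lambda, R0 and T for a config, via the same renewal
    solver the empirical life table uses (n = 0 marks the analytic origin)."""
    sched = analytic_schedule(config).to_schedule()
    R0 = float(sched.lm_x.sum())
    r = solve_intrinsic_rate(sched, tol=tol)
    lam, T = derived_rates(r, R0, sched)
    return DemographicParams(r=r, lambda_=lam, R0=R0, T=T, n=0, x_max=sched.x_max)
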