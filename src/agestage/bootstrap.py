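"""Bootstrap inference for life-table statistics and paired treatment tests.

The resampling unit is the individual (one whole life history): each
replicate draws n individuals with replacement from the cohort and recomputes
the requested statistics -- the demographic parameters r, lambda, R0, T and
any of the trait means.  Replicates in which no resampled female reproduces
have no defined r, lambda or T; those replicates are recorded as NaN,
excluded from the bootstrap mean/SE and counted in ``n_undefined`` (R0 = 0 is
retained).  Treatments are compared with the paired bootstrap test: the
percentile confidence interval of the replicate-by-replicate difference, the
pair being replicate i of each treatment's independent bootstrap stream.

All replicate computation is vectorised: a replicate is a multiplicity
vector over individuals, so the resampled egg schedule and trait means are
matrix products, and the renewal equation is solved for all replicates at
once by bracketed bisection.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, TRAIT_NAMES, individual_trait
from .lifetable import LifeTable

__all__ = [
    "BootstrapConfig",
    "StatBoot",
    "BootstrapSummary",
    "PairedTestResult",
    "bootstrap_estimates",
    "paired_bootstrap_test",
    "letter_groups",
    "compare_treatments",
    "treatment_seed",
]

PARAM_STATISTICS = ("r", "lambda", "R0", "T")
DEFAULT_STATISTICS = PARAM_STATISTICS + TRAIT_NAMES


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate count B (the study used 100,000; keep smaller for tests),
    RNG seed and significance level alpha."""

    B: int = 1000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class StatBoot:
    """Bootstrap record for one statistic: full-cohort point estimate,
    bootstrap mean/SE over defined replicates, and the replicate vector
    (length B, NaN marking undefined replicates)."""

    name: str
    point: float
    boot_mean: float
    boot_se: float
    n_undefined: int
    replicates: np.ndarray

    @property
    def defined_replicates(self) -> np.ndarray:
        return self.replicates[~np.isnan(self.replicates)]


@dataclass
class BootstrapSummary:
    label: str
    config: BootstrapConfig
    stats: dict[str, StatBoot]

    def __getitem__(self, name: str) -> StatBoot:
        return self.stats[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": list(self.stats),
                "point": [s.point for s in self.stats.values()],
                "boot_mean": [s.boot_mean for s in self.stats.values()],
                "boot_se": [s.boot_se for s in self.stats.values()],
                "n_undefined": [s.n_undefined for s in self.stats.values()],
            }
        )


# ---------------------------------------------------------------------------
# replicate engines


def _solve_r_many(lm: np.ndarray, iterations: int = 90) -> np.ndarray:
    """Vectorised renewal-equation root: one r per row of lm (NaN where the
    row has no reproduction).  Same bracket-and-bisect scheme as the scalar
    solver in :mod:`agestage.lifetable`."""
    B, width = lm.shape
    x1 = np.arange(1, width + 1, dtype=float)
    R0 = lm.sum(axis=1)
    ok = R0 > 0

    def residual(r: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            terms = np.exp(-np.outer(r, x1)) * lm
            terms = np.where(lm > 0, terms, 0.0)  # exp overflow only matters where lm > 0
            return terms.sum(axis=1) - 1.0

    lo = np.full(B, -1.0)
    hi = np.full(B, 2.0)
    for _ in range(60):
        bad = ok & (residual(lo) <= 0)
        if not bad.any():
            break
        lo[bad] *= 2.0
    for _ in range(60):
        bad = ok & (residual(hi) >= 0)
        if not bad.any():
            break
        hi[bad] *= 2.0
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        above = residual(mid) > 0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    r = 0.5 * (lo + hi)
    return np.where(ok, r, np.nan)


class _ReplicateEngine:
    """Precomputed per-individual arrays enabling vectorised replicates."""

    def __init__(self, cohort: Cohort):
        self.cohort = cohort
        self.n = cohort.n
        width = cohort.x_max + 1
        self.eggs = np.zeros((self.n, width))
        for i, ind in enumerate(cohort.individuals):
            self.eggs[i, : ind.lifespan] = ind.eggs
        self.trait_values: dict[str, np.ndarray] = {}
        self.trait_defined: dict[str, np.ndarray] = {}
        for name in TRAIT_NAMES:
            vals = np.array(
                [
                    v if (v := individual_trait(ind, name)) is not None else 0.0
                    for ind in cohort.individuals
                ]
            )
            defined = np.array(
                [individual_trait(ind, name) is not None for ind in cohort.individuals],
                dtype=float,
            )
            self.trait_values[name] = vals
            self.trait_defined[name] = defined

    def multiplicities(self, rng: np.random.Generator, B: int) -> np.ndarray:
        """B bootstrap replicates as multiplicity vectors over individuals
        (multinomial(n, uniform) == counting n draws with replacement)."""
        return rng.multinomial(self.n, np.full(self.n, 1.0 / self.n), size=B).astype(float)

    def statistics(self, C: np.ndarray, statistics: Sequence[str]) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        need_params = any(s in PARAM_STATISTICS for s in statistics)
        if need_params:
            lm = (C @ self.eggs) / self.n
            R0 = lm.sum(axis=1)
            if any(s in ("r", "lambda", "T") for s in statistics):
                r = _solve_r_many(lm)
                with np.errstate(invalid="ignore", divide="ignore"):
                    lam = np.exp(r)
                    T = np.where(np.abs(r) > 1e-10, np.log(R0) / r,
                                 (lm @ np.arange(1, lm.shape[1] + 1)) / np.where(R0 > 0, R0, np.nan))
            for s in statistics:
                if s == "R0":
                    out[s] = R0
                elif s == "r":
                    out[s] = r
                elif s == "lambda":
                    out[s] = lam
                elif s == "T":
                    out[s] = T
        for s in statistics:
            if s in TRAIT_NAMES:
                num = C @ (self.trait_values[s] * self.trait_defined[s])
                den = C @ self.trait_defined[s]
                with np.errstate(invalid="ignore", divide="ignore"):
                    out[s] = np.where(den > 0, num / den, np.nan)
        return out


def _point_estimates(cohort: Cohort, statistics: Sequence[str]) -> dict[str, float]:
    res = LifeTable(cohort, validate=False).fit(require_reproduction=False)
    points = {
        "r": res.params.r,
        "lambda": res.params.lambda_,
        "R0": res.params.R0,
        "T": res.params.T,
    }
    for name in TRAIT_NAMES:
        points[name] = res.traits[name].mean
    return {s: points[s] for s in statistics}


def bootstrap_estimates(
    cohort: Cohort,
    config: BootstrapConfig,
    statistics: Optional[Sequence[str]] = None,
) -> BootstrapSummary:
    """Bootstrap the selected statistics for one cohort.

    Reproducible: the same (cohort, B, seed) gives identical summaries.
    """
    if statistics is None:
        statistics = DEFAULT_STATISTICS
    unknown = [s for s in statistics if s not in DEFAULT_STATISTICS]
    if unknown:
        raise KeyError(f"unknown statistic(s) {unknown}; choose from {DEFAULT_STATISTICS}")
    engine = _ReplicateEngine(cohort)
    rng = np.random.default_rng(config.seed)
    C = engine.multiplicities(rng, config.B)
    reps = engine.statistics(C, statistics)
    points = _point_estimates(cohort, statistics)
    stats: dict[str, StatBoot] = {}
    for name in statistics:
        vec = reps[name]
        defined = vec[~np.isnan(vec)]
        stats[name] = StatBoot(
            name=name,
            point=points[name],
            boot_mean=float(defined.mean()) if defined.size else float("nan"),
            boot_se=float(defined.std(ddof=1)) if defined.size > 1 else float("nan"),
            n_undefined=int(np.isnan(vec).sum()),
            replicates=vec,
        )
    return BootstrapSummary(label=cohort.label, config=config, stats=stats)


# ---------------------------------------------------------------------------
# paired tests and letter displays


@dataclass(frozen=True)
class PairedTestResult:
    """Paired bootstrap comparison of one statistic between two treatments:
    difference of bootstrap means and the percentile CI of the
    replicate-by-replicate differences; significant iff the CI excludes 0."""

    statistic: str
    mean_diff: float
    ci_low: float
    ci_high: float
    alpha: float
    significant: bool
    n_pairs: int


def paired_bootstrap_test(
    a: BootstrapSummary,
    b: BootstrapSummary,
    statistic: str,
    alpha: float = 0.05,
) -> PairedTestResult:
    """Percentile-CI test on d_i = a_i - b_i, pairing replicate i with
    replicate i.  Pairs where either replicate is undefined are dropped."""
    ra, rb = a[statistic].replicates, b[statistic].replicates
    if len(ra) != len(rb):
        raise ValueError(
            f"replicate counts differ ({len(ra)} vs {len(rb)}); "
            "paired tests need equal B"
        )
    d = ra - rb
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError(f"no defined replicate pairs for {statistic!r}")
    lo, hi = np.quantile(d, [alpha / 2.0, 1.0 - alpha / 2.0])
    significant = bool(lo > 0.0 or hi < 0.0)
    return PairedTestResult(
        statistic=statistic,
        mean_diff=float(d.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        alpha=alpha,
        significant=significant,
        n_pairs=int(d.size),
    )


def _compact_letters(ordered: Sequence[str], significant_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display (insert-and-absorb) over a significance graph.

    ``ordered`` lists treatments in descending order of means; treatments not
    significantly different share a letter, intransitive patterns get
    multiple letters.
    """
    sets: list[frozenset] = [frozenset(ordered)]
    for i, j in itertools.combinations(ordered, 2):
        if frozenset((i, j)) not in significant_pairs:
            continue
        nxt: list[frozenset] = []
        for grp in sets:
            if i in grp and j in grp:
                nxt.extend((grp - {i}, grp - {j}))
            else:
                nxt.append(grp)
        # drop empties, duplicates and sets absorbed by a superset
        nxt = [g for g in dict.fromkeys(nxt) if g]
        sets = [g for g in nxt if not any(g < h for h in nxt)]
    rank = {t: k for k, t in enumerate(ordered)}
    sets.sort(key=lambda g: min(rank[t] for t in g))
    letters = {t: "" for t in ordered}
    for g, char in zip(sets, string.ascii_lowercase):
        for t in ordered:
            if t in g:
                letters[t] += char
    return letters


def letter_groups(
    summaries: Sequence[BootstrapSummary],
    statistic: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs paired bootstrap tests plus a compact letter display.

    Letters are assigned in descending order of bootstrap means; no
    multiple-testing correction is applied across the pairs (the unadjusted
    paired tests of the source framework).
    """
    if len(summaries) < 2:
        raise ValueError("letter groups need at least 2 treatments")
    means = {s.label: s[statistic].boot_mean for s in summaries}
    ordered = sorted(means, key=lambda t: -means[t])
    by_label = {s.label: s for s in summaries}
    sig = set()
    for i, j in itertools.combinations(ordered, 2):
        res = paired_bootstrap_test(by_label[i], by_label[j], statistic, alpha=alpha)
        if res.significant:
            sig.add(frozenset((i, j)))
    letters = _compact_letters(ordered, sig)
    return pd.DataFrame(
        {
            "statistic": statistic,
            "treatment": ordered,
            "mean": [means[t] for t in ordered],
            "se": [by_label[t][statistic].boot_se for t in ordered],
            "letter": [letters[t] for t in ordered],
        }
    )


def treatment_seed(master_seed: int, index: int) -> int:
    """Deterministic per-treatment seed derived by a fixed prime offset."""
    return int((master_seed + 7919 * index) % (2**31))


def compare_treatments(
    cohorts: Mapping[str, Cohort],
    config: BootstrapConfig,
    statistics: Optional[Sequence[str]] = None,
) -> tuple[dict[str, BootstrapSummary], pd.DataFrame, pd.DataFrame]:
    """Bootstrap every treatment (independent streams, seeds offset from the
    master seed), run all-pairs paired tests and build letter displays.

    Returns (summaries, comparison table, letters table)."""
    if len(cohorts) < 2:
        raise ValueError("need at least 2 treatments to compare")
    if statistics is None:
        statistics = DEFAULT_STATISTICS
    summaries: dict[str, BootstrapSummary] = {}
    for i, (label, cohort) in enumerate(cohorts.items()):
        cfg = BootstrapConfig(B=config.B, seed=treatment_seed(config.seed, i), alpha=config.alpha)
        if cohort.label != label:
            cohort = Cohort(individuals=cohort.individuals, label=label)
        summaries[label] = bootstrap_estimates(cohort, cfg, statistics=statistics)
    rows = []
    for stat in statistics:
        for a, b in itertools.combinations(summaries, 2):
            res = paired_bootstrap_test(summaries[a], summaries[b], stat, alpha=config.alpha)
            rows.append(
                {
                    "statistic": stat,
                    "treatment_a": a,
                    "treatment_b": b,
                    "mean_diff": res.mean_diff,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "significant": res.significant,
                }
            )
    compare = pd.DataFrame(rows)
    letters = pd.concat(
        [letter_groups(list(summaries.values()), stat, alpha=config.alpha) for stat in statistics],
        ignore_index=True,
    )
    return summaries, compare, letters
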