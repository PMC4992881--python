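import numpy as np
import pytest

from agestage.bootstrap import (
    BootstrapConfig,
    BootstrapSummary,
    StatBoot,
    bootstrap_estimates,
    compare_treatments,
    letter_groups,
    paired_bootstrap_test,
    treatment_seed,
)
from agestage.cohort import Cohort, IndividualRecord
from agestage.simulate import generate_cohort, preset


def fake_summary(label: str, name: str, replicates, alpha: float = 0.05) -> BootstrapSummary:
    reps = np.asarray(replicates, dtype=float)
    stat = StatBoot(
        name=name,
        point=float(np.nanmean(reps)),
        boot_mean=float(np.nanmean(reps)),
        boot_se=float(np.nanstd(reps, ddof=1)),
        n_undefined=int(np.isnan(reps).sum()),
        replicates=reps,
    )
    return BootstrapSummary(
        label=label, config=BootstrapConfig(B=len(reps), seed=0, alpha=alpha),
        stats={name: stat},
    )


def clone_cohort(k: int = 6) -> Cohort:
    inds = tuple(
        IndividualRecord(f"c{i}", ("egg", "larva", "pupa", "female", "female"),
                         (0, 0, 0, 3, 2))
        for i in range(k)
    )
    return Cohort(inds, label="clones")


class TestConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            BootstrapConfig(B=1)
        with pytest.raises(ValueError):
            BootstrapConfig(B=10, alpha=0.0)
        with pytest.raises(ValueError):
            BootstrapConfig(B=10, alpha=1.5)


class TestEstimates:
    def test_clone_cohort_has_zero_se(self):
        bs = bootstrap_estimates(clone_cohort(), BootstrapConfig(B=60, seed=4))
        for name, stat in bs.stats.items():
            if not np.isnan(stat.boot_se):
                # identical replicates; tolerance only absorbs fp noise in np.std
                assert stat.boot_se <= 1e-12 * max(1.0, abs(stat.boot_mean)), name

    def test_reproducible_given_seed(self, toy_cohort):
        cfg = BootstrapConfig(B=100, seed=12)
        a = bootstrap_estimates(toy_cohort, cfg)
        b = bootstrap_estimates(toy_cohort, cfg)
        for name in a.stats:
            assert np.array_equal(
                a[name].replicates, b[name].replicates, equal_nan=True
            ), name

    def test_two_replicates_exactly(self, toy_cohort):
        bs = bootstrap_estimates(toy_cohort, BootstrapConfig(B=2, seed=7),
                                 statistics=("R0",))
        assert len(bs["R0"].replicates) == 2

    def test_boot_mean_near_point(self, toy_cohort):
        bs = bootstrap_estimates(toy_cohort, BootstrapConfig(B=200, seed=3),
                                 statistics=("R0",))
        stat = bs["R0"]
        assert stat.point == 2.25
        assert abs(stat.boot_mean - 2.25) <= 3 * stat.boot_se

    def test_unknown_statistic_rejected(self, toy_cohort):
        with pytest.raises(KeyError):
            bootstrap_estimates(toy_cohort, BootstrapConfig(B=5, seed=0),
                                statistics=("R0", "bogus"))

    def test_undefined_replicates_counted(self):
        # one reproducing female among four individuals: a resample misses
        # her with probability (3/4)^4 ~ 0.316; those replicates have no r
        fem = IndividualRecord("f", ("egg", "female"), (0, 2))
        males = tuple(
            IndividualRecord(f"m{i}", ("egg", "male"), (0, 0)) for i in range(3)
        )
        cohort = Cohort((fem,) + males, "sparse")
        bs = bootstrap_estimates(cohort, BootstrapConfig(B=600, seed=9),
                                 statistics=("r", "R0"))
        frac = bs["r"].n_undefined / 600
        assert 0.25 < frac < 0.40
        assert bs["R0"].n_undefined == 0  # R0 = 0 replicates are retained
        reps = bs["R0"].replicates
        assert (reps[~np.isnan(reps)] == 0).sum() == bs["r"].n_undefined

    def test_every_individual_reproducing_means_no_undefined(self):
        bs = bootstrap_estimates(clone_cohort(), BootstrapConfig(B=50, seed=2),
                                 statistics=("r",))
        assert bs["r"].n_undefined == 0

    def test_boot_mean_converges_to_point(self, small_config):
        # drift of the bootstrap mean of R0 below 2% at B = 10,000, n = 150
        cohort = generate_cohort(small_config, n=150, seed=21)
        bs = bootstrap_estimates(cohort, BootstrapConfig(B=10_000, seed=1),
                                 statistics=("R0",))
        drift = abs(bs["R0"].boot_mean - bs["R0"].point) / bs["R0"].point
        assert drift < 0.02


class TestPairedTest:
    def test_identical_replicates_not_significant(self):
        reps = np.linspace(1.0, 2.0, 100)
        a = fake_summary("a", "R0", reps)
        b = fake_summary("b", "R0", reps)
        res = paired_bootstrap_test(a, b, "R0")
        assert res.mean_diff == 0.0
        assert not res.significant

    def test_constant_shift_gives_point_ci(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, 200)
        res = paired_bootstrap_test(
            fake_summary("a", "R0", base + 5), fake_summary("b", "R0", base), "R0"
        )
        assert res.ci_low == pytest.approx(5.0)
        assert res.ci_high == pytest.approx(5.0)
        assert res.significant

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError, match="replicate counts differ"):
            paired_bootstrap_test(
                fake_summary("a", "R0", np.arange(10.0)),
                fake_summary("b", "R0", np.arange(12.0)),
                "R0",
            )

    def test_significant_iff_ci_excludes_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.normal(rng.normal(0, 1), 1.0, 150)
            res = paired_bootstrap_test(
                fake_summary("a", "R0", d), fake_summary("b", "R0", np.zeros(150)), "R0"
            )
            assert res.significant == (res.ci_low > 0 or res.ci_high < 0)


class TestLetterGroups:
    def test_all_pairs_significant(self):
        rng = np.random.default_rng(1)
        summaries = [
            fake_summary(lbl, "R0", mean + rng.normal(0, 0.1, 200))
            for lbl, mean in (("hot", 5.0), ("warm", 10.0), ("cold", 1.0))
        ]
        table = letter_groups(summaries, "R0")
        assert table["treatment"].tolist() == ["warm", "hot", "cold"]
        assert table["letter"].tolist() == ["a", "b", "c"]

    def test_no_pair_significant_shares_one_letter(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 2.0, 300)
        summaries = [
            fake_summary(lbl, "R0", mean + base + rng.normal(0, 2.0, 300))
            for lbl, mean in (("a1", 10.0), ("a2", 10.1), ("a3", 9.9))
        ]
        table = letter_groups(summaries, "R0")
        assert set(table["letter"]) == {"a"}

    def test_intransitive_pattern(self):
        # means 10, 9, 5 with only (10 vs 9) non-significant
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1.5, 400)
        top = fake_summary("t10", "R0", 10 + noise + rng.normal(0, 1.5, 400))
        mid = fake_summary("t9", "R0", 9 + noise + rng.normal(0, 1.5, 400))
        low = fake_summary("t5", "R0", 5 + noise * 0.1)
        table = letter_groups([top, mid, low], "R0").set_index("treatment")
        assert table.loc["t10", "letter"] == "a"
        assert table.loc["t9", "letter"] == "a"
        assert table.loc["t5", "letter"] == "b"
        # sanity: the intended significance pattern actually held
        assert not paired_bootstrap_test(top, mid, "R0").significant
        assert paired_bootstrap_test(top, low, "R0").significant
        assert paired_bootstrap_test(mid, low, "R0").significant


class TestCompareTreatments:
    def test_same_cohort_twice_mostly_not_significant(self, small_config):
        cohort = generate_cohort(small_config, n=100, seed=17)
        twin = Cohort(cohort.individuals, label="twin")
        _, comp, letters = compare_treatments(
            {"orig": cohort, "twin": twin},
            BootstrapConfig(B=400, seed=6),
            statistics=("R0", "fecundity"),
        )
        # same data, independent streams: differences are pure noise
        assert not comp["significant"].any()
        for stat in ("R0", "fecundity"):
            sub = letters[letters["statistic"] == stat]
            assert set(sub["letter"]) == {"a"}

    def test_distant_presets_differ_in_fecundity(self):
        hits = 0
        for seed in range(5):
            cohorts = {
                "27C": generate_cohort(preset("27C"), n=150, seed=300 + seed),
                "36C": generate_cohort(preset("36C"), n=150, seed=800 + seed),
            }
            _, comp, _ = compare_treatments(
                cohorts, BootstrapConfig(B=500, seed=seed), statistics=("fecundity",)
            )
            hits += int(comp["significant"].iloc[0])
        # analytic means 125 vs 42 eggs: nearly every draw separates them
        assert hits >= 4

    def test_requires_two_treatments(self, toy_cohort):
        with pytest.raises(ValueError, match="at least 2"):
            compare_treatments({"only": toy_cohort}, BootstrapConfig(B=10, seed=0))

    def test_treatment_seeds_fixed_offsets(self):
        assert treatment_seed(42, 0) == 42
        assert treatment_seed(42, 1) == 42 + 7919
        assert 0 <= treatment_seed(2**31 - 1, 5) < 2**31
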