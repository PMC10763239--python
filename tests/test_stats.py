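"""Mixed model, cage z-scores, gated test selection and effect sizes."""

import numpy as np
import pandas as pd
import pytest

from ethoquartet.model import GroupDesign
from ethoquartet.simulate import simulate_null_phenotype
from ethoquartet.stats import (
    cage_zscore_profile,
    cohens_d,
    fit_genotype_lmm,
    gated_two_sample_test,
)
from ethoquartet.stats import test_vs_value as one_sample_test


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [2.0, 1.0, 3.0]) == pytest.approx(0.0)

    def test_one_pooled_sd_apart(self):
        a = np.array([0.0, 1.0, 2.0])
        b = a + 1.0  # same SD, means differ by exactly 1 pooled SD
        assert cohens_d(b, a) == pytest.approx(1.0)

    def test_hand_example(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(1.0, 2.0, size=12)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_undefined(self):
        assert np.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))


class TestGatedTests:
    def test_normal_samples_select_t(self):
        """Two clean normal samples pass the Shapiro and variance gates and
        get a Student t-test for most draws."""
        rng = np.random.default_rng(3)
        chosen = [
            gated_two_sample_test(
                rng.normal(size=20), rng.normal(size=20)
            ).test
            for _ in range(40)
        ]
        assert chosen.count("t") > 25

    def test_skewed_sample_selects_nonparametric(self):
        rng = np.random.default_rng(4)
        chosen = [
            gated_two_sample_test(
                rng.lognormal(0, 1.5, size=25), rng.normal(size=25)
            ).test
            for _ in range(20)
        ]
        assert chosen.count("mann-whitney") > 15

    def test_identical_paired_samples_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = gated_two_sample_test(a, a.copy(), paired=True)
        assert res.degenerate
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            gated_two_sample_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_one_sample_gate_records_choice(self):
        rng = np.random.default_rng(5)
        res = one_sample_test(rng.normal(0.5, 1.0, size=15), 0.0)
        assert res.test in {"one-sample-t", "wilcoxon"}
        assert "shapiro_p" in res.gates


class TestLMM:
    def test_effect_recovery_sign(self):
        df = simulate_null_phenotype(
            n_cages=8, cage_sd=1.0, noise_sd=1.0, effect=3.0, seed=6
        )
        res = fit_genotype_lmm(df)
        assert res.beta > 0
        assert res.p < 0.01
        assert res.se > 0
        assert np.isfinite(res.log_likelihood)

    def test_constant_values_flagged(self):
        df = pd.DataFrame(
            {
                "value": [1.0] * 8,
                "genotype": ["wt", "del"] * 4,
                "cage": ["c0"] * 4 + ["c1"] * 4,
            }
        )
        res = fit_genotype_lmm(df)
        assert res.singular

    def test_single_cage_rejected(self):
        df = simulate_null_phenotype(n_cages=1, seed=0)
        with pytest.raises(ValueError, match="cage"):
            fit_genotype_lmm(df)

    def test_single_genotype_rejected(self):
        df = simulate_null_phenotype(n_cages=4, seed=0)
        df["genotype"] = "wt"
        with pytest.raises(ValueError, match="genotype"):
            fit_genotype_lmm(df)

    def test_value_mapping_with_design(self):
        design = GroupDesign(
            genotype={"a": "wt", "b": "del", "c": "wt", "d": "del",
                      "e": "wt", "f": "del", "g": "wt", "h": "del"},
            sex={},
            cage={k: ("c0" if k < "e" else "c1") for k in "abcdefgh"},
        )
        rng = np.random.default_rng(7)
        values = {k: float(rng.normal()) for k in "abcdefgh"}
        res = fit_genotype_lmm(values, design)
        assert res.n == 8
        assert res.n_groups == 2


class TestCageZScores:
    def _design(self, n_cages=1):
        genotype, cage = {}, {}
        for c in range(n_cages):
            for i, g in enumerate(["wt", "wt", "del", "del"]):
                aid = f"c{c}a{i}"
                genotype[aid] = g
                cage[aid] = f"c{c}"
        return GroupDesign(genotype=genotype, sex={}, cage=cage)

    def test_hand_computed_z(self):
        """Cage values {1,2,3,4}: SD = 1.2910, so the animal at 3 has
        z = (3 - 2.5) / 1.2910 = 0.3873."""
        design = self._design()
        values = {"c0a0": 1.0, "c0a1": 2.0, "c0a2": 3.0, "c0a3": 4.0}
        prof = cage_zscore_profile(values, design)
        assert prof.z["c0a2"] == pytest.approx(0.3873, abs=1e-4)

    def test_cage_zscores_sum_to_zero_unit_sd(self):
        rng = np.random.default_rng(8)
        design = self._design(n_cages=5)
        values = {a: float(rng.normal(10, 3)) for a in design.animals}
        for cage_id in design.cages():
            members = design.cage_members(cage_id)
            vals = np.array([values[a] for a in members])
            z = (vals - vals.mean()) / vals.std(ddof=1)
            assert z.sum() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=1) == pytest.approx(1.0)
        prof = cage_zscore_profile(values, design)
        # profile reproduces the same z for the del animals
        for cage_id in design.cages():
            members = design.cage_members(cage_id)
            vals = np.array([values[a] for a in members])
            for a, v in zip(members, vals):
                if design.genotype[a] == "del":
                    expected = (v - vals.mean()) / vals.std(ddof=1)
                    assert prof.z[a] == pytest.approx(expected)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        design = self._design(n_cages=4)
        values = {a: float(rng.normal()) for a in design.animals}
        scaled = {a: 7.5 * v + 3.0 for a, v in values.items()}
        p1 = cage_zscore_profile(values, design)
        p2 = cage_zscore_profile(scaled, design)
        for a in p1.z:
            assert p1.z[a] == pytest.approx(p2.z[a])

    def test_del_at_cage_mean_gives_null_test(self):
        design = self._design(n_cages=4)
        values = {}
        for cage_id in design.cages():
            members = design.cage_members(cage_id)
            # wt at +/-1, del both exactly at the cage mean 0
            for a in members:
                values[a] = 0.0 if design.genotype[a] == "del" else (
                    1.0 if a.endswith("0") else -1.0
                )
        prof = cage_zscore_profile(values, design)
        assert all(z == pytest.approx(0.0) for z in prof.z.values())
        assert prof.test.degenerate or prof.test.p > 0.9

    def test_zero_sd_cage_excluded(self):
        design = self._design(n_cages=2)
        values = {a: 1.0 for a in design.cage_members("c0")}
        values.update(
            {a: float(i) for i, a in enumerate(design.cage_members("c1"))}
        )
        with pytest.warns(UserWarning, match="zero SD"):
            prof = cage_zscore_profile(values, design)
        assert prof.excluded_cages == ["c0"]
        assert all(a.startswith("c1") for a in prof.z)
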