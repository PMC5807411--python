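import numpy as np
import pytest

from ramanecm.phantom import PhantomParams, make_phantom, sample_assay
from ramanecm.quantify import DepthProfile, lateral_average
from ramanecm.validate import (pair_profiles, r_squared, rmsep, two_way_anova,
                               validate_constituent)
from ramanecm.phantom import SectionedAssay


def balanced_anova_oracle(values, a_levels, b_levels, reps):
    """Explicit cell-mean decomposition for a balanced two-way layout.

    values indexed [a, b, rep]. For balanced designs type-I/II/III sums
    of squares coincide, so this is an exact independent oracle.
    """
    y = np.asarray(values, dtype=float).reshape(a_levels, b_levels, reps)
    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    cell = y.mean(axis=2)
    ss_a = b_levels * reps * np.sum((mean_a - grand) ** 2)
    ss_b = a_levels * reps * np.sum((mean_b - grand) ** 2)
    ss_int = reps * np.sum(
        (cell - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_res = np.sum((y - cell[:, :, None]) ** 2)
    return ss_a, ss_b, ss_int, ss_res


class TestPairProfiles:
    def _assay(self, depths, values):
        return SectionedAssay(np.asarray(depths),
                              {"GAG": np.asarray(values, dtype=float)},
                              len(depths))

    def test_exact_values_at_coinciding_depths(self):
        prof = DepthProfile(np.array([0.1, 0.2, 0.3]), np.array([1.0, 2.0, 3.0]))
        paired = pair_profiles(prof, self._assay([0.1, 0.3], [9.0, 9.0]), "GAG")
        np.testing.assert_allclose(paired[:, 1], [1.0, 3.0])

    def test_linear_midpoint(self):
        prof = DepthProfile(np.array([0.0001, 1.0]), np.array([0.0, 10.0]))
        paired = pair_profiles(prof, self._assay([0.5, 0.9], [1.0, 1.0]), "GAG")
        assert paired[0, 1] == pytest.approx(5.0, rel=1e-3)

    def test_out_of_range_depths_clamped_with_warning(self):
        prof = DepthProfile(np.array([0.5, 1.0]), np.array([2.0, 4.0]))
        with pytest.warns(UserWarning, match="clamping"):
            paired = pair_profiles(prof, self._assay([0.1, 2.0], [1.0, 1.0]),
                                   "GAG")
        np.testing.assert_allclose(paired[:, 1], [2.0, 4.0])

    def test_single_section_raises(self):
        prof = DepthProfile(np.array([0.5, 1.0]), np.array([2.0, 4.0]))
        with pytest.raises(ValueError):
            pair_profiles(prof, SectionedAssay(np.array([0.7]),
                                               {"GAG": np.array([1.0])}, 1),
                          "GAG")


class TestRSquared:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert r_squared(np.array([1.0, 2.0, 3.0]),
                         np.array([1.0, 3.0, 2.0])) == pytest.approx(0.25)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(99)
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        assert r_squared(x, y) < 0.02

    def test_constant_series_raises(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.arange(5.0))


class TestRMSEP:
    def test_perfect_prediction_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rmsep(x, x) == 0.0

    def test_hand_computed_example(self):
        assert rmsep(np.array([1.0, 1.0]), np.array([1.0, 3.0])) == \
            pytest.approx(70.7107, abs=1e-3)

    def test_scale_invariance(self):
        pred = np.array([1.0, 2.0, 2.5])
        obs = np.array([1.2, 1.8, 2.9])
        assert rmsep(3.7 * pred, 3.7 * obs) == pytest.approx(rmsep(pred, obs))

    def test_nonpositive_observed_mean_raises(self):
        with pytest.raises(ValueError):
            rmsep(np.array([1.0]), np.array([-2.0]))


class TestTwoWayAnova:
    def test_matches_cell_mean_oracle_over_random_balanced_designs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = int(rng.integers(2, 4))       # up to 3 technique levels
            b = int(rng.integers(2, 9))       # up to 8 depth levels
            r = int(rng.integers(2, 5))       # up to 4 replicates
            y = rng.standard_normal(a * b * r)
            tech = np.repeat(np.arange(a), b * r)
            depth = np.tile(np.repeat(np.arange(b), r), a)
            table = two_way_anova(y, tech, depth, include_interaction=True)
            ss_a, ss_b, ss_int, ss_res = balanced_anova_oracle(y, a, b, r)
            assert abs(table.loc["technique", "sum_sq"] - ss_a) < 1e-8
            assert abs(table.loc["depth", "sum_sq"] - ss_b) < 1e-8
            assert abs(table.loc["interaction", "sum_sq"] - ss_int) < 1e-8
            assert abs(table.loc["residual", "sum_sq"] - ss_res) < 1e-8

    def test_all_equal_values_zero_ss_p_one(self):
        y = np.full(12, 3.3)
        tech = np.repeat([0, 1], 6)
        depth = np.tile(np.repeat([0, 1, 2], 2), 2)
        table = two_way_anova(y, tech, depth)
        assert (table["sum_sq"] == 0).all()
        assert (table["p"] == 1.0).all()

    def test_injected_technique_offset_detected(self):
        rng = np.random.default_rng(5)
        depth = np.tile(np.arange(6), 8)
        tech = np.repeat([0, 1], 24)
        base = np.tile(rng.standard_normal(6), 8)
        y = base + 0.1 * rng.standard_normal(48) + 2.0 * (tech == 1)
        table = two_way_anova(y, tech, depth)
        assert table.loc["technique", "p"] < 0.05

    def test_single_replicate_drops_interaction(self):
        y = np.arange(8.0)
        tech = np.repeat([0, 1], 4)
        depth = np.tile(np.arange(4), 2)
        table = two_way_anova(y, tech, depth)
        assert "interaction" not in table.index

    def test_empty_cells_with_interaction_raises(self):
        y = np.arange(6.0)
        tech = np.array([0, 0, 0, 1, 1, 1])
        depth = np.array([0, 1, 2, 0, 0, 1])  # cell (1, 2) empty
        with pytest.raises(ValueError, match="empty cells"):
            two_way_anova(y, tech, depth, include_interaction=True)

    def test_type_one_error_rate_near_alpha(self):
        """Under the null (no technique effect) the technique p-value
        should be uniform: rejection fraction ~ alpha."""
        rng = np.random.default_rng(123)
        depth = np.tile(np.arange(8), 2)
        tech = np.repeat([0, 1], 8)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            base = np.tile(rng.standard_normal(8), 2)
            y = base + 0.3 * rng.standard_normal(16)
            table = two_way_anova(y, tech, depth)
            hits += table.loc["technique", "p"] < 0.05
        assert abs(hits / n_sim - 0.05) <= 0.02


class TestValidateConstituent:
    def _noiseless_setup(self):
        params = PhantomParams.reduced("native", n_cols=6, lateral_cv=0.0,
                                       baseline_amplitude=0.0,
                                       baseline_poly_scale=0.0, noise_frac=0.0)
        _, truth = make_phantom("native", params, seed=3)
        assay = sample_assay(truth, n_sections=8, noise_cv=0.0)
        prof = lateral_average(truth.concentration_fields["GAG"],
                               truth.pixel_size_um, "GAG")
        return prof, assay

    def test_noiseless_self_consistency(self):
        prof, assay = self._noiseless_setup()
        report = validate_constituent(prof, assay, "GAG",
                                      scheme="peak_anchor", anchor_depth_mm=1.4)
        assert report.r_squared > 0.99
        assert report.rmsep_percent < 2.0
        assert report.p_value("technique") > 0.05

    def test_offset_assay_flags_technique_effect(self):
        prof, assay = self._noiseless_setup()
        shifted = SectionedAssay(
            assay.section_mid_depths_mm,
            {"GAG": assay.concentrations["GAG"] * 1.5},
            assay.n_sections)
        # compare without re-normalizing so the offset survives
        report = validate_constituent(prof, shifted, "GAG")
        assert report.p_value("technique") < 0.05

    def test_single_section_assay_raises(self):
        prof, _ = self._noiseless_setup()
        assay = SectionedAssay(np.array([1.0]), {"GAG": np.array([2.0])}, 1)
        with pytest.raises(ValueError):
            validate_constituent(prof, assay, "GAG")

    def test_metrics_invariant_to_common_rescaling(self):
        prof, assay = self._noiseless_setup()
        r1 = validate_constituent(prof, assay, "GAG")
        scaled_prof = DepthProfile(prof.depths_mm, prof.values * 3.0)
        scaled_assay = SectionedAssay(
            assay.section_mid_depths_mm,
            {"GAG": assay.concentrations["GAG"] * 3.0}, assay.n_sections)
        r2 = validate_constituent(scaled_prof, scaled_assay, "GAG")
        assert r2.r_squared == pytest.approx(r1.r_squared)
        assert r2.rmsep_percent == pytest.approx(r1.rmsep_percent)
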