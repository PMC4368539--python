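"""Design construction, effect archetypes, and the measurement generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rppatterns as rp
from rppatterns import PatternCode
from rppatterns.simulate import GROUP_LABELS


class TestDesign:
    def test_eight_groups_times_n_mice(self):
        mice, _ = rp.build_design(rp.DesignSpec(n_mice_per_group=8))
        assert len(mice) == 64
        assert mice.groupby("group").size().eq(8).all()
        assert mice["mouse_id"].is_unique

    def test_spot_grid_is_full_factorial(self):
        spec = rp.DesignSpec(
            n_mice_per_group=8, n_proteins=2, regions=["hippocampus"],
            fractions=["nuclear"], n_dilution_steps=5, n_replicates=3,
        )
        _, grid = rp.build_design(spec)
        assert len(grid) == 2 * 1 * 1 * 64 * 5 * 3  # 1920 spots
        per_mouse = grid.groupby(["protein", "mouse_id"]).size()
        assert per_mouse.eq(15).all()

    def test_mouse_to_group_is_a_function(self):
        _, grid = rp.build_design(rp.DesignSpec(n_proteins=1))
        assert grid.groupby("mouse_id")["group"].nunique().eq(1).all()

    @pytest.mark.parametrize("bad", [
        dict(n_mice_per_group=0), dict(n_proteins=-1), dict(n_replicates=0),
        dict(regions=[]), dict(dilution_factor=0.0),
    ])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            rp.DesignSpec(**bad)


class TestArchetypes:
    def test_fl_eq_nl_example_means(self):
        means = rp.archetype_to_effects(PatternCode.FL_EQ_NL, 20, 0)
        assert means == pytest.approx({
            "c-SC-sal": 1.0, "c-CS-sal": 1.2, "c-SC-mem": 1.0, "c-CS-mem": 1.2,
            "t-SC-sal": 1.0, "t-CS-sal": 1.2, "t-SC-mem": 1.0, "t-CS-mem": 1.2,
        })

    def test_b_comp_contrasts(self):
        c = rp.contrasts_from_effects(rp.archetype_to_effects(PatternCode.B_COMP, 20, 20))
        assert c["B"] == pytest.approx(20)
        assert c["NL"] == pytest.approx(20)
        assert c["FL"] == pytest.approx(0)
        assert c["RL"] == pytest.approx(0)

    def test_stable_means_all_equal(self):
        means = rp.archetype_to_effects(PatternCode.STABLE, 0, 0)
        assert len(set(means.values())) == 1

    @pytest.mark.parametrize("code", list(PatternCode))
    def test_contrast_consistency_all_archetypes(self, code):
        """Recomputing the nine contrasts from the 8 means reproduces the plant."""
        from rppatterns.simulate import _archetype_contrasts, _DEFAULT_BASELINE_FRACTION

        m, b = 30.0, 30.0 * _DEFAULT_BASELINE_FRACTION.get(code, 1.0)
        planted = _archetype_contrasts(code, m, b)
        got = rp.contrasts_from_effects(rp.archetype_to_effects(code, m, b))
        for comp, v in planted.items():
            assert got[comp] == pytest.approx(v, abs=1e-9), comp
        assert got["B-cm"] == pytest.approx(0.0)

    @settings(max_examples=40, deadline=None)
    @given(m=st.floats(-60, 150), b=st.floats(-40, 60))
    def test_contrast_consistency_property(self, m, b):
        got = rp.contrasts_from_effects(rp.archetype_to_effects(PatternCode.B_PLUS_FL, m, b))
        assert got["NL"] == pytest.approx(m, abs=1e-9)
        assert got["B"] == pytest.approx(b, abs=1e-9)
        assert got["FL"] == pytest.approx(m - b, abs=1e-9)

    def test_unknown_archetype_lists_valid_codes(self):
        with pytest.raises(ValueError, match="FL_EQ_NL"):
            rp.archetype_to_effects("NOT_A_CODE", 20)

    def test_magnitude_below_minus_100_rejected(self):
        with pytest.raises(ValueError, match="-100"):
            rp.archetype_to_effects(PatternCode.FL_EQ_NL, -100.0)


class TestSimulateMeasurements:
    def test_zero_noise_normalized_equals_planted_mean(self, small_design, small_effects):
        df = rp.simulate_measurements(small_design, small_effects, rp.ZERO_NOISE, seed=3)
        norm = rp.normalize_to_total_protein(df)
        merged = norm.merge(
            small_effects.melt(
                id_vars=["protein", "region", "fraction"],
                var_name="group", value_name="true_mean",
            ),
            on=["protein", "region", "fraction", "group"],
        )
        assert np.allclose(merged["normalized_intensity"], merged["true_mean"])

    def test_seed_determinism_byte_identical(self, small_design, small_effects):
        noise = rp.NoiseSpec()
        a = rp.simulate_measurements(small_design, small_effects, noise, seed=7)
        b = rp.simulate_measurements(small_design, small_effects, noise, seed=7)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = rp.simulate_measurements(small_design, small_effects, noise, seed=8)
        assert not a["raw_intensity"].equals(c["raw_intensity"])

    def test_sypro_halves_down_the_dilution_series(self, small_design, small_effects):
        df = rp.simulate_measurements(small_design, small_effects, rp.ZERO_NOISE, seed=3)
        by_step = df.groupby("dilution_step")["sypro_intensity"].first()
        assert np.allclose(by_step.values, 2.0 ** -(by_step.index.values - 1.0))

    def test_missing_effect_entry_names_instance(self, small_design, small_effects):
        with pytest.raises(ValueError, match="P002"):
            rp.simulate_measurements(
                small_design, small_effects[small_effects.protein != "P002"],
                rp.ZERO_NOISE, seed=1,
            )

    def test_forced_low_signal_instance_is_discarded_downstream(self, small_design, small_effects):
        noise = rp.NoiseSpec(low_signal_rate=1.0)
        df = rp.simulate_measurements(small_design, small_effects, noise, seed=5)
        pre = rp.preprocess(df)
        assert pre["qc_low_signal"].all()
        assert not rp.usable_mask(pre).any()

    def test_outliers_inflate_spot_residuals(self, small_design, small_effects):
        def log_dev(noise):
            df = rp.normalize_to_total_protein(
                rp.simulate_measurements(small_design, small_effects, noise, seed=9)
            )
            merged = df.merge(
                small_effects.melt(
                    id_vars=["protein", "region", "fraction"],
                    var_name="group", value_name="true_mean",
                ),
                on=["protein", "region", "fraction", "group"],
            )
            return np.abs(np.log(merged["normalized_intensity"] / merged["true_mean"]))

        clean = log_dev(rp.NoiseSpec())
        dirty = log_dev(rp.NoiseSpec(outlier_rate=0.2, outlier_scale=10.0))
        assert (clean > 1.0).sum() == 0
        assert (dirty > 1.0).sum() > 0

    def test_noise_spec_validation(self):
        with pytest.raises(ValueError):
            rp.NoiseSpec(sd_mouse=-0.1)
        with pytest.raises(ValueError):
            rp.NoiseSpec(outlier_rate=1.5)
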