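"""Unquenched fractions and the nonspecific-quenching-corrected efficiency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmfret.quench import (
    DataQualityError,
    condition_efficiencies,
    fret_efficiency_corrected,
    net_intensity,
    patch_unquenched_fractions,
    read_patch_table,
    state_name,
    summarize_condition,
    unquenched_fraction,
)
from tmfret.synthetic_data import (
    DEFAULT_TRUTH,
    expected_unquenched_fraction,
    simulate_patch_cohort,
)


class TestNetIntensity:
    def test_subtraction(self):
        assert net_intensity(100.0, 20.0) == 80.0

    def test_zero_net_rejected_with_patch_id(self):
        with pytest.raises(DataQualityError, match="p7"):
            net_intensity(50.0, 50.0, patch_id="p7")

    def test_generator_patches_all_positive(self):
        df = simulate_patch_cohort(DEFAULT_TRUTH, n_patches=4, seed=11)
        out = patch_unquenched_fractions(df)
        assert (out["F"] > 0).all()


class TestUnquenchedFraction:
    def test_no_quenching(self):
        assert unquenched_fraction(80.0, 80.0) == 1.0

    def test_half_quenched(self):
        assert unquenched_fraction(40.0, 80.0) == 0.5

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            unquenched_fraction(10.0, 0.0)

    def test_cohort_mean_recovers_truth(self):
        # 50 with-site patches at known true F, 3% intensity noise
        df = simulate_patch_cohort(DEFAULT_TRUTH, n_patches=50, seed=3)
        out = patch_unquenched_fractions(df)
        grp = out[
            (out["state"] == "inactivated") & out["has_site"]
        ]
        e_true = DEFAULT_TRUTH.true_efficiency("inactivated")
        f_true = expected_unquenched_fraction(e_true, DEFAULT_TRUTH.f_ns)
        assert grp["F"].mean() == pytest.approx(f_true, abs=0.02)


class TestCorrectedEfficiency:
    def test_reduces_to_one_minus_F_without_nonspecific(self):
        assert fret_efficiency_corrected(0.6, 1.0) == pytest.approx(0.4)

    def test_pure_nonspecific_gives_zero(self):
        assert fret_efficiency_corrected(0.8, 0.8) == pytest.approx(0.0)

    def test_hand_evaluated_grid(self):
        # 20-case grid frozen from direct evaluation of the correction
        f_sites = np.linspace(0.3, 0.75, 4)
        f_nos = np.linspace(0.8, 1.1, 5)
        for fs in f_sites:
            for fn in f_nos:
                expected = (fn - fs) / (fs * fn + fn - fs)
                assert fret_efficiency_corrected(fs, fn) == pytest.approx(
                    expected, abs=1e-12
                )
        # one fully hand-worked case: (0.8-0.4)/(0.32+0.8-0.4) = 0.5555...
        assert fret_efficiency_corrected(0.4, 0.8) == pytest.approx(
            0.5555555555555555, abs=1e-12
        )

    def test_clipping_warns_on_noise_overshoot(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert fret_efficiency_corrected(1.05, 1.0) == 0.0

    @given(
        fs=st.floats(0.2, 0.9),
        fn=st.floats(0.5, 1.0),
        delta=st.floats(0.01, 0.1),
    )
    @settings(derandomize=True, max_examples=150)
    def test_monotonicity(self, fs, fn, delta):
        if fs >= fn:
            return
        e = fret_efficiency_corrected(fs, fn, clip=False)
        # decreasing in F_site
        if fs + delta < fn:
            assert fret_efficiency_corrected(fs + delta, fn, clip=False) < e
        # increasing in F_no_site while F_site < F_no_site
        if fn + delta <= 1.2:
            assert fret_efficiency_corrected(fs, fn + delta, clip=False) > e


class TestSummaries:
    def _table(self, f_values, has_site=True, voltage=0, ligand="cAMP"):
        rows = []
        for i, f in enumerate(f_values):
            rows.append(
                {
                    "patch_id": f"p{i}",
                    "construct": "x",
                    "has_site": has_site,
                    "voltage_mV": voltage,
                    "ligand": ligand,
                    "fl_roi_no_metal": 1000.0 + 50.0,
                    "bg_no_metal": 50.0,
                    "fl_roi_metal": 1000.0 * f + 50.0,
                    "bg_metal": 50.0,
                }
            )
        return pd.DataFrame(rows)

    def test_single_patch_sem_missing(self):
        s = summarize_condition(self._table([0.5]))
        assert s.loc[0, "n"] == 1
        assert np.isnan(s.loc[0, "F_sem"])

    def test_identical_patches(self):
        s = summarize_condition(self._table([0.5] * 4))
        assert s.loc[0, "F_mean"] == pytest.approx(0.5)
        assert s.loc[0, "F_sem"] == pytest.approx(0.0, abs=1e-12)
        assert s.loc[0, "n"] == 4

    def test_cohort_mean_within_2_sem_of_truth(self):
        df = simulate_patch_cohort(DEFAULT_TRUTH, n_patches=5, seed=21)
        s = summarize_condition(df)
        e_true = DEFAULT_TRUTH.true_efficiency("resting-apo")
        f_true = expected_unquenched_fraction(e_true, DEFAULT_TRUTH.f_ns)
        row = s[
            (s["site_class"] == "with_site")
            & (s["voltage_mV"] == 0)
            & (s["ligand"] == "none")
        ].iloc[0]
        assert abs(row["F_mean"] - f_true) < 2 * row["F_sem"] + 1e-9

    def test_missing_condition_named_in_error(self):
        df = self._table([0.5, 0.6], has_site=True)
        with pytest.raises(ValueError, match="without-site"):
            condition_efficiencies(df)

    def test_pipeline_identity_raw_vs_predivided(self):
        # efficiency from raw ROI tables equals efficiency from F values
        df = pd.concat(
            [
                self._table([0.5, 0.55, 0.45], has_site=True),
                self._table([0.9, 0.95, 0.85], has_site=False),
            ],
            ignore_index=True,
        )
        from_raw = condition_efficiencies(df)
        with_f = patch_unquenched_fractions(df)
        from_f = condition_efficiencies(with_f)
        assert from_raw.loc[0, "efficiency_mean"] == pytest.approx(
            from_f.loc[0, "efficiency_mean"], rel=1e-12
        )

    def test_zero_noise_recovery_is_exact(self):
        df = simulate_patch_cohort(DEFAULT_TRUTH, n_patches=3, seed=0, noise=False)
        eff = condition_efficiencies(df)
        for _, row in eff.iterrows():
            assert row["efficiency_mean"] == pytest.approx(
                DEFAULT_TRUTH.true_efficiency(row["state"]), abs=1e-9
            )


class TestIO:
    def test_reader_validates_columns_and_vocab(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"patch_id": ["a"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            read_patch_table(path)
        df = simulate_patch_cohort(DEFAULT_TRUTH, n_patches=2, seed=5)
        good = tmp_path / "good.csv"
        df.to_csv(good, index=False)
        assert len(read_patch_table(good)) == len(df)
        df_bad = df.copy()
        df_bad.loc[0, "ligand"] = "caffeine"
        bad2 = tmp_path / "bad2.csv"
        df_bad.to_csv(bad2, index=False)
        with pytest.raises(ValueError, match="caffeine"):
            read_patch_table(bad2)

    def test_state_names(self):
        assert state_name(0, "cAMP") == "resting-cAMP"
        assert state_name(0, "none") == "resting-apo"
        assert state_name(-100, "cAMP") == "activated"
        assert state_name(-100, "none") == "inactivated"
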