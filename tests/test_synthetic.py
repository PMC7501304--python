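"""Ground-truth cohort generator: planted couplings, AR sampling, fixtures."""

import json

import numpy as np
import pytest

from glassyhrv.io import read_manifest, read_rr_series
from glassyhrv.preprocess import autocorrelation, standardize
from glassyhrv.synthetic import (
    CLASS_PRESETS,
    ClassPreset,
    ar_spectral_radius,
    make_dataset,
    make_raw_rr,
    planted_couplings,
    sample_autoregressive,
    spectral_shaped_noise,
)
from tests.conftest import make_standardized


class TestPlantedCouplings:
    def test_magnitudes_follow_power_law(self):
        preset = ClassPreset("H", A=0.2, beta=1.0)
        planted = planted_couplings(preset, 3, "all_positive", seed=0)
        assert planted.J_true == pytest.approx([0.2, 0.1, 0.2 / 3], rel=1e-12)

    def test_random_signs_reproducible(self):
        preset = CLASS_PRESETS["AF"]
        a = planted_couplings(preset, 30, "random", seed=5)
        b = planted_couplings(preset, 30, "random", seed=5)
        assert np.array_equal(a.J_true, b.J_true)
        assert set(np.sign(a.J_true)) == {-1.0, 1.0}  # frustration present

    def test_magnitude_strictly_decreasing(self):
        for preset in CLASS_PRESETS.values():
            planted = planted_couplings(preset, 50, "random", seed=1)
            mag = np.abs(planted.J_true)
            assert np.all(np.diff(mag) < 0)

    def test_stationarity_enforced(self):
        # all-positive couplings with beta ~ 1 sum past 1 and need rescaling
        preset = ClassPreset("CD", A=0.37, beta=1.2)
        planted = planted_couplings(preset, 100, "all_positive", seed=0)
        assert planted.spectral_radius < 1.0
        assert 0.0 < planted.rescale_factor <= 1.0
        raw = 0.37 * np.arange(1, 101.0) ** -1.2
        assert planted.J_true == pytest.approx(raw * planted.rescale_factor, rel=1e-12)

    def test_long_run_variance_stable(self):
        planted = planted_couplings(CLASS_PRESETS["AF"], 40, "random", seed=2)
        z = sample_autoregressive(planted, 40_000, seed=3)
        first, second = z.values[:20_000], z.values[20_000:]
        assert abs(first.var() - second.var()) / second.var() < 0.1


class TestSampleAutoregressive:
    def test_white_noise_limit(self):
        planted = planted_couplings(ClassPreset("H", A=1e-12, beta=1.0), 5, "all_positive", 0)
        z = sample_autoregressive(planted, 10_000, seed=1)
        acf = autocorrelation(z, 1)
        assert abs(acf.values[1]) < 3.0 / np.sqrt(10_000)

    def test_ar1_matches_yule_walker(self):
        """AR(1) with J = 0.5: C(tau) = 0.5^tau (closed form)."""
        preset = ClassPreset("H", A=0.5, beta=0.0)  # flat magnitude, single lag
        planted = planted_couplings(preset, 1, "all_positive", 0)
        z = sample_autoregressive(planted, 100_000, seed=4)
        acf = autocorrelation(z, 5)
        n = 100_000
        for tau in range(1, 6):
            expected = 0.5**tau
            se = np.sqrt((1 - expected**2) / n) * 3  # generous MC band
            assert acf.values[tau] == pytest.approx(expected, abs=5 * se + 0.01)

    def test_seed_reproducibility(self):
        planted = planted_couplings(CLASS_PRESETS["H"], 20, "random", seed=7)
        a = sample_autoregressive(planted, 5000, seed=9)
        b = sample_autoregressive(planted, 5000, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_output_standardized(self):
        planted = planted_couplings(CLASS_PRESETS["CD"], 30, "random", seed=1)
        z = sample_autoregressive(planted, 8000, seed=2)
        assert abs(z.values.mean()) < 1e-12
        assert np.mean(z.values**2) == pytest.approx(1.0, abs=1e-12)


class TestMakeRawRR:
    def test_inverse_of_standardize_example(self):
        z = make_standardized([800.0, 1000.0])
        rr = make_raw_rr(z, 900.0, 100.0)
        assert rr.intervals == pytest.approx([800.0, 1000.0])

    def test_round_trip_long_series(self, rng):
        z = make_standardized(rng.standard_normal(10_000))
        rr = make_raw_rr(z, 820.0, 45.0, patient_id="x", class_label="H")
        back = standardize(rr)
        assert np.max(np.abs(back.values - z.values)) < 1e-9

    def test_nonpositive_intervals_rejected(self, rng):
        z = make_standardized(rng.standard_normal(100))
        with pytest.raises(ValueError, match="mean_ms"):
            make_raw_rr(z, 50.0, 25.0)  # ~2-sigma excursions go negative


class TestSpectralShapedNoise:
    def test_seed_reproducibility(self):
        a = spectral_shaped_noise(1.0, 2048, seed=3)
        b = spectral_shaped_noise(1.0, 2048, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_gamma_bounds_enforced(self):
        with pytest.raises(ValueError):
            spectral_shaped_noise(2.5, 2048, seed=0)
        with pytest.raises(ValueError):
            spectral_shaped_noise(1.0, 3000, seed=0)  # not a power of two

    @pytest.mark.parametrize("gamma", [0.0, 0.5, 1.0, 1.5])
    def test_planted_exponent_recovered(self, gamma):
        from glassyhrv.spectral import fit_psd_power_law, welch_psd

        z = spectral_shaped_noise(gamma, 1 << 17, seed=17)
        est = welch_psd(z, 4096)
        fit = fit_psd_power_law(est, (2e-4, 1e-2))
        assert fit.gamma == pytest.approx(gamma, abs=0.05)


class TestMakeDataset:
    def test_cohort_structure_and_round_trip(self, tmp_path):
        presets = {k: CLASS_PRESETS[k] for k in ("H", "AF", "CD")}
        manifest = make_dataset(presets, 2, N=500, T=10, seed=42, out_dir=tmp_path)
        assert manifest.class_counts() == {"H": 2, "AF": 2, "CD": 2}
        reloaded = read_manifest(tmp_path / "manifest.csv")
        assert reloaded.class_counts() == {"H": 2, "AF": 2, "CD": 2}
        for rec in reloaded.records:
            rr = read_rr_series(rec.path, rec.patient_id, rec.class_label)
            z = standardize(rr)
            assert abs(z.values.mean()) < 1e-12
        truths = json.loads((tmp_path / "truths.json").read_text())
        assert set(truths) == {r.patient_id for r in manifest.records}
        for entry in truths.values():
            assert len(entry["J_true"]) == 10
            assert ar_spectral_radius(entry["J_true"]) < 1.0

    def test_dataset_reproducible_from_seed(self, tmp_path):
        m1 = make_dataset({"H": CLASS_PRESETS["H"]}, 1, 300, 5, 7, tmp_path / "a")
        m2 = make_dataset({"H": CLASS_PRESETS["H"]}, 1, 300, 5, 7, tmp_path / "b")
        r1 = read_rr_series(m1.records[0].path)
        r2 = read_rr_series(m2.records[0].path)
        assert np.array_equal(r1.intervals, r2.intervals)
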