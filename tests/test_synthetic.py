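"""Synthetic campaign generator: chamber dynamics, device response models,
contamination mechanism, and reproducibility."""

import numpy as np
import pytest

import radon_pt as rp
from radon_pt.synthetic import _assign_codes


class TestChamber:
    def test_default_true_exposures_near_campaign_anchors(self, windows, rng):
        params = rp.ChamberParams()
        series, truth = rp.simulate_chamber(params, windows, rng)
        # frozen regression band: E1 within 20% of 356, E2 within 20% of 1014
        assert abs(truth["E1"] - 356) / 356 < 0.20
        assert abs(truth["E2"] - 1014) / 1014 < 0.20

    def test_backbone_end_of_window_anchors(self):
        params = rp.ChamberParams()
        hours = np.arange(71.0)
        c = params.backbone(hours)
        assert c[13] == pytest.approx(30.0, rel=0.01)  # ~30 kBq/m3 at end of E1
        assert c[70] < 2.0  # under 2 kBq/m3 at end of E2
        assert c.min() >= 0.3 and c.max() <= 32.0

    def test_constant_plateau_limit(self, windows, rng):
        params = rp.ChamberParams(
            baseline_concentration=27.5,
            plateau_concentration=27.5,
            rise_rate=1e6,
            decay_rate=1e-9,
            noise_cv=0.0,
        )
        series, truth = rp.simulate_chamber(params, windows, rng)
        assert truth["E1"] == pytest.approx(27.5 * 13)
        assert truth["E2"] == pytest.approx(27.5 * 70)

    def test_window_outside_span_rejected(self, rng):
        from datetime import datetime

        w = rp.ExposureWindow("w", datetime(2019, 1, 1), datetime(2019, 1, 2), 0.2)
        series, _ = rp.simulate_chamber(rp.ChamberParams(), rp.default_windows(), rng)
        with pytest.raises(rp.CoverageError):
            rp.integrate_exposure(series, w)


class TestPassiveGroup:
    CODE = rp.parse_code("L05P1")

    def test_noiseless_limit(self, rng):
        model = rp.DeviceModel(rp.DeviceKind.PASSIVE, reporting_cv=0.0)
        sub = rp.simulate_passive_group(self.CODE, "E1", 356.0, model, rng)
        assert (sub.exposure, sub.u_k1) == (356.0, 0.0)

    def test_degassing_bias_shifts_mean(self):
        model = rp.DeviceModel(rp.DeviceKind.PASSIVE, degassing_factor=1.6)
        reported = [
            rp.simulate_passive_group(
                self.CODE, "E1", 356.0, model, np.random.default_rng(s)
            ).exposure
            for s in range(300)
        ]
        assert np.mean(reported) == pytest.approx(356.0 * 1.6, rel=0.01)

    def test_degassing_not_applied_when_disabled(self, rng):
        model = rp.DeviceModel(rp.DeviceKind.PASSIVE, reporting_cv=0.0, degassing_factor=1.6)
        sub = rp.simulate_passive_group(
            self.CODE, "E2", 940.0, model, rng, apply_degassing=False
        )
        assert sub.exposure == pytest.approx(940.0)

    def test_standard_error_law(self):
        model = rp.DeviceModel(rp.DeviceKind.PASSIVE, n_detectors=10, reporting_cv=0.10)
        ratios = [
            (lambda s: s.u_k1 / s.exposure)(
                rp.simulate_passive_group(self.CODE, "E1", 356.0, model, np.random.default_rng(s))
            )
            for s in range(400)
        ]
        assert np.mean(ratios) == pytest.approx(0.10 / np.sqrt(10), rel=0.08)

    def test_transit_background_subtraction_is_negligible(self, rng):
        model = rp.DeviceModel(rp.DeviceKind.PASSIVE, reporting_cv=0.0)
        sub = rp.simulate_passive_group(
            self.CODE, "E1", 356.0, model, rng, storage_exposure=0.384
        )
        assert sub.exposure == pytest.approx(356.0, abs=1e-9)

    def test_single_detector_rejected(self):
        with pytest.raises(ValueError):
            rp.DeviceModel(rp.DeviceKind.PASSIVE, n_detectors=1)


class TestActiveMonitor:
    CODE = rp.parse_code("L03A1")

    def _chamber(self, rng):
        series, _ = rp.simulate_chamber(rp.ChamberParams(noise_cv=0.0), rp.default_windows(), rng)
        return series

    def test_high_sensitivity_has_small_relative_error(self, rng, windows):
        chamber = self._chamber(rng)
        model = rp.DeviceModel(rp.DeviceKind.ACTIVE, sensitivity_cpm_per_kBqm3=50.0)
        _, subs = rp.simulate_active_monitor(self.CODE, chamber, model, windows, rng)
        truth = {l: rp.integrate_exposure(chamber, w) for l, w in windows.items()}
        for sub in subs:
            assert abs(sub.exposure - truth[sub.window_label]) / truth[sub.window_label] < 0.01
            assert sub.u_k1 / sub.exposure < 0.01

    def test_hourly_counting_error_law_at_plateau(self, windows):
        # ionization chamber (50 cpm at 1 kBq/m3) at the 30 kBq/m3 plateau:
        # 90000 expected counts/h, so hourly scatter ~1/sqrt(counts) ~ 0.33%
        from datetime import datetime

        ts = np.datetime64(datetime(2018, 11, 5, 12), "s") + np.arange(
            200
        ) * np.timedelta64(3600, "s")
        chamber = rp.MonitorSeries(None, ts, np.full(200, 30.0))
        model = rp.DeviceModel(rp.DeviceKind.ACTIVE, sensitivity_cpm_per_kBqm3=50.0)
        series, _ = rp.simulate_active_monitor(
            self.CODE, chamber, model, {}, np.random.default_rng(3)
        )
        rel = np.std(series.concentration) / 30.0
        assert rel == pytest.approx(1 / np.sqrt(50 * 60 * 30), rel=0.25)
        assert rel < 0.01

    def test_low_sensitivity_noisier_than_high(self, windows):
        chamber = self._chamber(np.random.default_rng(0))
        devs = {}
        for sens in (50.0, 0.1):
            model = rp.DeviceModel(rp.DeviceKind.ACTIVE, sensitivity_cpm_per_kBqm3=sens)
            series, _ = rp.simulate_active_monitor(
                self.CODE, chamber, model, windows, np.random.default_rng(7)
            )
            devs[sens] = np.std(series.concentration - chamber.concentration)
        assert devs[0.1] > 5 * devs[50.0]

    def test_infinite_sensitivity_reproduces_truth(self, rng, windows):
        chamber = self._chamber(rng)
        model = rp.DeviceModel(rp.DeviceKind.ACTIVE, sensitivity_cpm_per_kBqm3=np.inf)
        series, subs = rp.simulate_active_monitor(self.CODE, chamber, model, windows, rng)
        np.testing.assert_allclose(series.concentration, chamber.concentration)
        assert all(s.u_k1 == 0.0 for s in subs)


class TestGenerateCampaign:
    def test_default_counts_match_campaign(self, default_campaign):
        subs, series, truth = default_campaign
        assert sum(s.window_label == "E1" for s in subs) == 45
        assert sum(s.window_label == "E2" for s in subs) == 41
        assert len(series) == 22
        assert len(truth.contaminated_codes) == 5
        assert all(c.device_kind is rp.DeviceKind.PASSIVE for c in truth.contaminated_codes)

    def test_same_seed_bit_identical(self):
        a = rp.generate_campaign(seed=42)
        b = rp.generate_campaign(seed=42)
        assert a[0] == b[0]
        for sa, sb in zip(a[1], b[1]):
            np.testing.assert_array_equal(sa.concentration, sb.concentration)
        assert a[2].true_exposures == b[2].true_exposures

    def test_different_seeds_differ(self):
        a = rp.generate_campaign(seed=1)
        b = rp.generate_campaign(seed=2)
        assert a[0] != b[0]

    def test_zero_contamination(self):
        cfg = rp.CampaignConfig(contaminated_fraction=0.0)
        _, _, truth = rp.generate_campaign(cfg, seed=3)
        assert truth.contaminated_codes == []
        assert all(m.degassing_factor == 1.0 for m in truth.device_models.values())

    def test_degassing_applies_to_first_window_only(self, default_campaign):
        subs, _, truth = default_campaign
        by_key = {(str(s.code), s.window_label): s for s in subs}
        e2_truth = truth.true_exposures["E2"]
        for code in truth.contaminated_codes:
            e1 = by_key[(str(code), "E1")]
            assert e1.exposure > 1.25 * truth.true_exposures["E1"]
            if (str(code), "E2") in by_key:
                e2 = by_key[(str(code), "E2")]
                assert abs(e2.exposure - e2_truth) / e2_truth < 0.2

    def test_truth_exposure_consistent_with_chamber_series(self, default_campaign, windows):
        _, _, truth = default_campaign
        for label, w in windows.items():
            assert truth.true_exposures[label] == pytest.approx(
                rp.integrate_exposure(truth.chamber_series, w)
            )

    def test_invalid_contaminated_fraction(self):
        with pytest.raises(ValueError):
            rp.CampaignConfig(contaminated_fraction=1.5)

    def test_code_assignment_unique(self):
        codes = _assign_codes(23, rp.DeviceKind.PASSIVE, 20)
        assert len(set(codes)) == 23
        assert max(c.lab_number for c in codes) <= 20
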