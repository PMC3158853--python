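"""Targeted XIC extraction and peak quantification: window conventions,
peak detection, isotope-distribution gating, and ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest

import xicquant as xq
from conftest import single_peak_run


def _gaussian_run(height=1000.0, tr=5.0, sigma_s=7.5, mz=500.0,
                  interval_s=2.5, length_min=10.0):
    """Single-trace Gaussian peak at one m/z."""
    times = np.arange(0.0, length_min * 60.0, interval_s) / 60.0
    prof = height * np.exp(-0.5 * ((times - tr) / (sigma_s / 60.0)) ** 2)
    scans = [xq.Ms1Scan(t, np.array([mz]), np.array([v]))
             for t, v in zip(times, prof)]
    return xq.MsRun("gauss", scans), times


def _flat_envelope(mz=500.0, z=1):
    return xq.IsotopeEnvelope(
        mz + np.arange(3) * xq.chem.ISOTOPE_SPACING / z,
        np.array([1.0, 0.5, 0.2]))


class TestBuildXic:
    def test_trace_equals_sampled_gaussian(self, clean_dataset):
        cfg, run, truth, peptides = clean_dataset
        rec = peptides[0]
        env = rec.ion.envelope()
        xic = xq.build_xic(run, env, rec.ion.reference_tR)
        amps = env.relative_abundances / env.relative_abundances.sum()
        t = truth.table.set_index("peptide_id").loc[rec.peptide_id]
        sigma = cfg.sigma_seconds / 60.0
        expected = np.exp(-0.5 * ((xic.times - t["tR_actual"]) / sigma) ** 2)
        expected = t["height_applied"] * expected
        floor = cfg.centroid_floor * t["height_applied"] * amps.max()
        for iso in range(3):
            full = amps[iso] * expected
            full[full <= floor] = 0.0
            np.testing.assert_allclose(xic.intensities[iso], full,
                                       rtol=1e-9, atol=1e-9)

    def test_empty_spectra_give_zero_traces(self):
        times = np.arange(0, 600, 2.5) / 60.0
        run = xq.MsRun("empty", [xq.Ms1Scan(t, np.array([]), np.array([]))
                                 for t in times])
        xic = xq.build_xic(run, _flat_envelope(), 5.0)
        assert xic is not None
        assert np.all(xic.intensities == 0)

    def test_ppm_window_closed_boundary(self):
        """A centroid at exactly +7.0 ppm is included; at +7.01 ppm it is
        excluded."""
        m = 500.0
        inside = m + m * 7.0 * 1e-6
        outside = m + m * 7.01 * 1e-6
        run = single_peak_run([inside], [[100.0]], [1.0])
        env = xq.IsotopeEnvelope(np.array([m, m + 1, m + 2]),
                                 np.array([1.0, 0.5, 0.2]))
        xic = xq.build_xic(run, env, 1.0, ppm=7.0)
        assert xic.intensities[0, 0] == 100.0
        run2 = single_peak_run([outside], [[100.0]], [1.0])
        xic2 = xq.build_xic(run2, env, 1.0, ppm=7.0)
        assert xic2.intensities[0, 0] == 0.0

    def test_max_centroid_selected_within_window(self):
        m = 500.0
        run = single_peak_run([m - m * 3e-6, m + m * 2e-6],
                              [[80.0, 120.0]], [1.0])
        env = xq.IsotopeEnvelope(np.array([m, m + 1, m + 2]),
                                 np.array([1.0, 0.5, 0.2]))
        xic = xq.build_xic(run, env, 1.0, ppm=7.0)
        assert xic.intensities[0, 0] == 120.0

    def test_no_scans_in_window_returns_none(self):
        run = single_peak_run([500.0], [[10.0]], [1.0])
        assert xq.build_xic(run, _flat_envelope(), 30.0, tR_window=5.0) is None


class TestDetectPeak:
    def test_noise_free_gaussian_height_and_area(self):
        h, sigma_s = 1000.0, 7.5
        run, _ = _gaussian_run(height=h, sigma_s=sigma_s)
        env = xq.IsotopeEnvelope(np.array([500.0, 501.0, 502.0]),
                                 np.array([1.0, 0.0, 0.0]))
        xic = xq.build_xic(run, env, 5.0)
        peak = xq.detect_peak(xic)
        # apex within sampling-grid error of the amplitude
        assert peak.apex_height == pytest.approx(h, rel=0.02)
        assert peak.area == pytest.approx(h * sigma_s * np.sqrt(2 * np.pi),
                                          rel=0.03)
        assert peak.left_bound <= peak.apex_time <= peak.right_bound
        assert peak.n_points >= 10

    def test_all_zero_trace_returns_none(self):
        run = single_peak_run([500.0], [[0.0], [0.0]], [1.0, 1.1])
        xic = xq.build_xic(run, _flat_envelope(), 1.0)
        assert xq.detect_peak(xic) is None

    def test_tallest_of_two_peaks_wins(self):
        times = np.arange(0, 600, 2.5) / 60.0
        trace = (100.0 * np.exp(-0.5 * ((times - 3.0) / 0.125) ** 2)
                 + 60.0 * np.exp(-0.5 * ((times - 7.0) / 0.125) ** 2))
        run = single_peak_run([500.0], [[v] for v in trace], times)
        xic = xq.build_xic(run, _flat_envelope(), 5.0, tR_window=5.0)
        peak = xq.detect_peak(xic)
        assert peak.apex_time == pytest.approx(3.0, abs=0.05)
        assert peak.apex_height == pytest.approx(100.0, rel=0.02)

    def test_bounds_stop_at_local_minimum(self):
        times = np.arange(0, 600, 2.5) / 60.0
        trace = (100.0 * np.exp(-0.5 * ((times - 4.0) / 0.125) ** 2)
                 + 90.0 * np.exp(-0.5 * ((times - 5.2) / 0.125) ** 2))
        run = single_peak_run([500.0], [[v] for v in trace], times)
        xic = xq.build_xic(run, _flat_envelope(), 4.5, tR_window=5.0)
        peak = xq.detect_peak(xic)
        assert peak.apex_time == pytest.approx(4.0, abs=0.05)
        assert peak.right_bound < 5.2  # integration stops in the valley


class TestIsotopeCorrelation:
    def _xic_with_apex(self, obs):
        times = np.array([1.0])
        return xq.Xic(times, np.array(obs, float).reshape(3, 1),
                      np.array([500.0, 501.0, 502.0]), 7.0)

    def test_proportional_observations_give_r_one(self):
        env = xq.IsotopeEnvelope(np.zeros(3), np.array([1.0, 0.53, 0.18]))
        xic = self._xic_with_apex([[820.0], [434.6], [147.6]])
        peak = xq.ChromPeak(1.0, 1402.2, 0.0, 1.0, 1.0, 1, 0)
        assert xq.isotope_correlation(xic, env, peak) == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        theo = np.array([1.0, 0.53, 0.18])
        obs = np.array([1000.0, 0.0, 180.0])
        env = xq.IsotopeEnvelope(np.zeros(3), theo)
        xic = self._xic_with_apex([[o] for o in obs])
        peak = xq.ChromPeak(1.0, obs.sum(), 0.0, 1.0, 1.0, 1, 0)
        # direct Pearson formula as the oracle
        ot, tt = obs - obs.mean(), theo - theo.mean()
        expected = (ot * tt).sum() / np.sqrt((ot ** 2).sum() * (tt ** 2).sum())
        assert xq.isotope_correlation(xic, env, peak) == \
            pytest.approx(expected, abs=1e-12)

    def test_constant_observation_rejected_as_zero(self):
        env = xq.IsotopeEnvelope(np.zeros(3), np.array([1.0, 0.53, 0.18]))
        xic = self._xic_with_apex([[500.0], [500.0], [500.0]])
        peak = xq.ChromPeak(1.0, 1500.0, 0.0, 1.0, 1.0, 1, 0)
        assert xq.isotope_correlation(xic, env, peak) == 0.0


class TestQuantify:
    def test_noise_free_recovery(self, clean_dataset):
        """Heights match the grid-sampled truth within 0.5% (they coincide
        to float precision); areas match the Gaussian closed form within
        3%; no missing cells."""
        _, run, truth, peptides = clean_dataset
        heights, areas, results = xq.quantify([run], peptides)
        t = truth.table.set_index("peptide_id")
        h = heights.values["run1"]
        assert h.isna().sum() == 0
        np.testing.assert_allclose(h, t.loc[h.index, "height_sampled"],
                                   rtol=5e-3)
        # amplitude recovery bounded by the sampling grid (<= 1.4% here)
        np.testing.assert_allclose(h, t.loc[h.index, "height_applied"],
                                   rtol=0.02)
        a = areas.values["run1"]
        np.testing.assert_allclose(a, t.loc[a.index, "area_applied"],
                                   rtol=0.03)

    def test_every_pair_attempted_and_reasons_exclusive(self, replicate_dataset):
        results = replicate_dataset["results"]
        n_runs = len(replicate_dataset["runs"])
        n_pep = len(replicate_dataset["peptides"])
        assert len(results) == n_runs * n_pep
        for r in results:
            if r.accepted:
                assert r.rejection_reason is None
                assert r.iso_correlation > 0.95
            else:
                assert r.rejection_reason in (
                    "no_signal", "low_iso_correlation", "out_of_tR_window")

    def test_tr_outside_gradient_is_na_with_reason(self, clean_dataset):
        _, run, _, peptides = clean_dataset
        far = xq.PeptideRecord(
            "far", xq.PeptideIon("PEPTIDEK", (), 2, 60.0))
        heights, _, results = xq.quantify([run], [far])
        assert np.isnan(heights.values.loc["far", "run1"])
        assert results[0].rejection_reason == "out_of_tR_window"

    def test_intensity_scale_equivariance(self, clean_dataset):
        """Doubling every spectrum doubles heights and areas exactly."""
        _, run, _, peptides = clean_dataset
        doubled = xq.MsRun("run1", [
            xq.Ms1Scan(s.scan_time, s.mz_array, 2.0 * s.intensity_array)
            for s in run.scans])
        h1, a1, _ = xq.quantify([run], peptides)
        h2, a2, _ = xq.quantify([doubled], peptides)
        pd.testing.assert_frame_equal(h2.values, 2.0 * h1.values)
        pd.testing.assert_frame_equal(a2.values, 2.0 * a1.values)

    def test_window_monotonicity(self, replicate_dataset):
        """Wider ppm / tR windows never decrease accepted quantifications."""
        runs = replicate_dataset["runs"][:2]
        peptides = replicate_dataset["peptides"][:30]
        accepted = []
        for ppm, win in [(3.0, 2.0), (7.0, 5.0), (14.0, 8.0)]:
            _, _, res = xq.quantify(runs, peptides,
                                    xq.QuantParams(ppm=ppm, tR_window=win))
            accepted.append(sum(r.accepted for r in res))
        assert accepted[0] <= accepted[1] <= accepted[2]

    def test_duplicate_peptide_ids_rejected(self, clean_dataset):
        _, run, _, peptides = clean_dataset
        with pytest.raises(ValueError, match="duplicate"):
            xq.quantify([run], [peptides[0], peptides[0]])

    def test_mono_only_reads_monoisotopic_trace(self, clean_dataset):
        _, run, _, peptides = clean_dataset
        rec = peptides[0]
        full = xq.quantify_one(run, rec)
        mono = xq.quantify_one(run, rec, xq.QuantParams(mono_only=True))
        env = rec.ion.envelope()
        frac = (env.relative_abundances / env.relative_abundances.sum())[0]
        assert mono.peak.apex_height == \
            pytest.approx(full.peak.apex_height * frac, rel=1e-9)
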