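"""Generator tests: geometry, waveforms, propagation, sampling/noise,
areas/pressures, cohort draws and copula calibration."""
import math

import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

from aortastiff.errors import CalibrationError, InvalidArgumentError
from aortastiff.synthetic import (LANDMARK_NAMES, MEASURES, CohortSpec,
                                  LogNormalMarginal, NormalMarginal,
                                  PressureRecord, SubjectTruth, WaveformParams,
                                  calibrate_copula, default_cohort_spec,
                                  draw_cohort, make_area_and_pressure,
                                  make_centerline, make_flow_waveform,
                                  propagate_waveform, sample_and_noise,
                                  waveform_function)
from conftest import dense_xcorr_delay


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------

class TestCenterline:
    def test_arc_length_matches_requested_total(self):
        cl = make_centerline(300.0, 200, seed=0)
        assert 297.0 <= cl.cumulative_arc_length[-1] <= 303.0

    def test_same_seed_is_bit_identical(self):
        a = make_centerline(330.0, 150, seed=7)
        b = make_centerline(330.0, 150, seed=7)
        assert np.array_equal(a.points, b.points)
        assert a.landmarks == b.landmarks

    def test_different_seeds_differ(self):
        a = make_centerline(330.0, 150, seed=1)
        b = make_centerline(330.0, 150, seed=2)
        assert not np.array_equal(a.points, b.points)

    def test_curve_is_not_straight(self):
        cl = make_centerline(300.0, 200, seed=0)
        chord = np.linalg.norm(cl.points[-1] - cl.points[0])
        assert chord < cl.total_length

    def test_landmarks_ordered_and_complete(self):
        cl = make_centerline(250.0, 64, seed=3)
        idx = [cl.landmarks[n] for n in LANDMARK_NAMES]
        assert idx == sorted(idx) and len(set(idx)) == 8

    @pytest.mark.parametrize("length,npts", [(100.0, 200), (500.0, 200),
                                             (300.0, 8)])
    def test_rejects_out_of_range_arguments(self, length, npts):
        with pytest.raises(InvalidArgumentError):
            make_centerline(length, npts)


# ---------------------------------------------------------------------------
# waveform template
# ---------------------------------------------------------------------------

class TestWaveform:
    def test_peak_value_at_time_to_peak(self, waveform_params):
        q = make_flow_waveform(waveform_params,
                               np.array([waveform_params.time_to_peak]))
        assert q[0] == pytest.approx(waveform_params.peak_flow, rel=0.01)

    def test_late_diastole_returns_to_baseline(self):
        p = WaveformParams(diastolic_fraction=0.0, baseline_flow=10.0)
        q = make_flow_waveform(p, np.array([0.9 * p.cardiac_period]))
        assert q[0] == pytest.approx(p.baseline_flow, abs=0.1)

    def test_peak_flow_scales_linearly_above_baseline(self, dense_time):
        base = WaveformParams(peak_flow=300.0, baseline_flow=20.0)
        double = WaveformParams(peak_flow=580.0, baseline_flow=20.0)
        qb = make_flow_waveform(base, dense_time) - 20.0
        qd = make_flow_waveform(double, dense_time) - 20.0
        assert np.allclose(qd, 2.0 * qb, atol=1e-9)

    def test_nonnegative_everywhere(self, flow_fn, dense_time):
        assert np.all(flow_fn(dense_time) >= 0.0)

    @pytest.mark.parametrize("kwargs", [
        {"cardiac_period": -1.0},
        {"time_to_peak": 0.05, "upslope_duration": 0.10},
        {"peak_flow": 10.0, "baseline_flow": 20.0},
        {"diastolic_fraction": 1.5},
    ])
    def test_inconsistent_params_rejected(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            WaveformParams(**kwargs)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

class TestPropagation:
    def test_interplane_delay_is_distance_over_pwv(self, flow_fn):
        cl = make_centerline(300.0, 200, seed=0)
        cur = propagate_waveform(flow_fn, cl, 4, 10.0)
        # planes at 0 and 100 mm: ground-truth delay 10 ms
        d = dense_xcorr_delay(cur.flow[0], cur.flow[1], cur.dt)
        assert d == pytest.approx(0.010, abs=cur.dt)

    def test_end_to_end_delay(self, flow_fn):
        cl = make_centerline(300.0, 200, seed=0)
        cur = propagate_waveform(flow_fn, cl, 10, 15.0)
        d = dense_xcorr_delay(cur.flow[0], cur.flow[-1], cur.dt)
        assert d == pytest.approx(0.020, abs=cur.dt)

    def test_propagation_exactness_all_pairs(self, flow_fn):
        """Cross-correlation delay between any two noise-free planes equals
        d/PWV to within the dense-grid step."""
        cl = make_centerline(330.0, 200, seed=1)
        pwv = 8.0
        cur = propagate_waveform(flow_fn, cl, 6, pwv)
        for i in range(6):
            for j in range(i + 1, 6):
                expect = (cur.plane_arc_lengths[j] -
                          cur.plane_arc_lengths[i]) / 1000.0 / pwv
                d = dense_xcorr_delay(cur.flow[i], cur.flow[j], cur.dt)
                assert d == pytest.approx(expect, abs=cur.dt)

    def test_zero_damping_preserves_amplitude(self, flow_fn):
        cl = make_centerline(300.0, 100, seed=0)
        cur = propagate_waveform(flow_fn, cl, 5, 10.0, damping=0.0)
        peaks = cur.flow.max(axis=1)
        # peak sample value varies only by dense-grid discretization
        assert np.allclose(peaks, peaks[0], rtol=1e-4)

    def test_damping_attenuates_downstream(self, flow_fn):
        cl = make_centerline(300.0, 100, seed=0)
        cur = propagate_waveform(flow_fn, cl, 5, 10.0, damping=1e-3)
        peaks = cur.flow.max(axis=1)
        assert np.all(np.diff(peaks) < 0)

    def test_invalid_pwv_rejected(self, flow_fn):
        cl = make_centerline(300.0, 100, seed=0)
        with pytest.raises(InvalidArgumentError):
            propagate_waveform(flow_fn, cl, 5, 0.0)


# ---------------------------------------------------------------------------
# sampling and noise
# ---------------------------------------------------------------------------

class TestSampling:
    def test_default_settings_give_50_phases(self, flow_fn):
        cl = make_centerline(300.0, 100, seed=0)
        cur = sample_and_noise(propagate_waveform(flow_fn, cl, 3, 10.0))
        assert cur.time_axis.size == 50
        assert cur.effective_dt == pytest.approx(0.034)

    def test_noise_free_preserves_peak_time_within_acquisition_dt(self, flow_fn):
        cl = make_centerline(300.0, 100, seed=0)
        dense = propagate_waveform(flow_fn, cl, 2, 10.0)
        cur = sample_and_noise(dense, snr_db=np.inf)
        t_peak_dense = dense.time_axis[np.argmax(dense.flow[0])]
        t_peak = cur.time_axis[np.argmax(cur.flow[0])]
        assert abs(t_peak - t_peak_dense) <= 0.034

    def test_noise_variance_matches_snr_definition(self, flow_fn):
        """Monte-Carlo check of the noise model: empirical noise variance
        over 1000 draws matches var(clean)/10^(SNR/10) within 10%."""
        cl = make_centerline(300.0, 100, seed=0)
        dense = propagate_waveform(flow_fn, cl, 2, 10.0, extent=(0.0, 0.5))
        clean = sample_and_noise(dense, snr_db=np.inf).flow[0]
        target = clean.var() / 10.0 ** (20.0 / 10.0)
        draws = np.array([sample_and_noise(dense, snr_db=20.0, seed=s).flow[0]
                          for s in range(1000)])
        noise_var = ((draws - clean) ** 2).mean()
        assert noise_var == pytest.approx(target, rel=0.10)

    def test_seeded_determinism(self, flow_fn):
        cl = make_centerline(300.0, 100, seed=0)
        dense = propagate_waveform(flow_fn, cl, 3, 10.0)
        a = sample_and_noise(dense, snr_db=20.0, seed=5)
        b = sample_and_noise(dense, snr_db=20.0, seed=5)
        assert np.array_equal(a.flow, b.flow)

    def test_nan_snr_rejected(self, flow_fn):
        cl = make_centerline(300.0, 100, seed=0)
        dense = propagate_waveform(flow_fn, cl, 3, 10.0)
        with pytest.raises(InvalidArgumentError):
            sample_and_noise(dense, snr_db=float("nan"))


# ---------------------------------------------------------------------------
# areas and pressures
# ---------------------------------------------------------------------------

def _subject(dist=2.0, sbp=130.0, dbp=80.0):
    return SubjectTruth(subject_id="s", group="CAD", true_pwv=10.0,
                        true_distensibility=dist, true_cf_pwv=10.0,
                        pressure=PressureRecord(sbp, dbp), heart_rate=60.0,
                        covariates={"infarcted_segments": 1})


class TestAreasAndPressure:
    def test_area_change_matches_distensibility_rule(self):
        aa, _, _ = make_area_and_pressure(_subject(2.0, 130.0, 80.0),
                                          amin_aa=800.0)
        assert aa.amax - aa.amin == pytest.approx(80.0)  # D*Amin*PP

    def test_published_scale_example(self):
        # ascending aorta diameter 35.1 mm -> Amin ~ 967.6 mm^2; central
        # pressures 118/81 -> PP 37; D = 1.71e-3 -> dA ~ 61.2 mm^2
        amin = math.pi * 35.1 ** 2 / 4.0
        aa, _, _ = make_area_and_pressure(_subject(1.71, 118.0, 81.0),
                                          amin_aa=amin)
        assert aa.amax - aa.amin == pytest.approx(61.2, abs=0.1)

    def test_pressure_record_pp_exact(self):
        p = PressureRecord(118.0, 81.0)
        assert p.pp == 37.0
        with pytest.raises(InvalidArgumentError):
            PressureRecord(80.0, 90.0)


# ---------------------------------------------------------------------------
# cohort draws
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def big_group():
    """10^5 patients drawn with an identity copula, reused across
    marginal-fidelity and independence tests."""
    spec = default_cohort_spec(n_cad=100_000, n_control=2)
    cohort = draw_cohort(spec, seed=42)
    vals = np.array([[s.drawn[m] for m in MEASURES]
                     for s in cohort if s.group == "CAD"])
    return spec, vals


class TestCohortDraws:
    def test_patient_pwv_4d_mean_matches_published(self, big_group):
        _, vals = big_group
        i = MEASURES.index("pwv_4d")
        assert vals[:, i].mean() == pytest.approx(17.3, rel=0.01)

    def test_marginal_fidelity_means_sds(self, big_group):
        spec, vals = big_group
        for m in ("cf_pwv", "pwv_2d", "pwv_4d"):
            marg = spec.marginals["CAD"][m]
            col = vals[:, MEASURES.index(m)]
            assert col.mean() == pytest.approx(marg.mean, rel=0.02)
            assert col.std() == pytest.approx(marg.sd, rel=0.02)

    def test_distensibility_median_iqr_fidelity(self, big_group):
        _, vals = big_group
        col = vals[:, MEASURES.index("distensibility")]
        q25, med, q75 = np.percentile(col, [25, 50, 75])
        assert med == pytest.approx(1.71, rel=0.02)
        assert q75 - q25 == pytest.approx(2.17 - 1.19, rel=0.05)

    def test_control_distensibility_median(self):
        spec = default_cohort_spec(n_cad=2, n_control=50_000)
        cohort = draw_cohort(spec, seed=9)
        col = np.array([s.drawn["distensibility"] for s in cohort
                        if s.group == "control"])
        assert np.median(col) == pytest.approx(1.77, rel=0.05)

    def test_identity_copula_gives_independent_measures(self, big_group):
        _, vals = big_group
        for i in range(4):
            for j in range(i + 1, 4):
                rho = spearmanr(vals[:, i], vals[:, j]).statistic
                assert abs(rho) < 0.02

    def test_same_seed_reproduces_cohort(self):
        spec = default_cohort_spec()
        a = draw_cohort(spec, seed=3)
        b = draw_cohort(spec, seed=3)
        assert all(x.drawn == y.drawn and x.pressure == y.pressure
                   for x, y in zip(a, b))

    def test_group_structure(self):
        cohort = draw_cohort(default_cohort_spec(), seed=0)
        cad = [s for s in cohort if s.group == "CAD"]
        ctl = [s for s in cohort if s.group == "control"]
        assert len(cad) == 35 and len(ctl) == 18
        assert all(s.covariates["infarcted_segments"] >= 1 for s in cad)
        assert all(s.covariates["infarcted_segments"] == 0 for s in ctl)

    def test_non_psd_copula_rejected(self):
        bad = np.array([[1.0, 0.9, 0.9, 0.0], [0.9, 1.0, -0.9, 0.0],
                        [0.9, -0.9, 1.0, 0.0], [0.0, 0.0, 0.0, 1.0]])
        spec = default_cohort_spec()
        with pytest.raises(InvalidArgumentError):
            CohortSpec(marginals=spec.marginals, copula=bad,
                       n_cad=35, n_control=18, aux=spec.aux)


# ---------------------------------------------------------------------------
# copula calibration
# ---------------------------------------------------------------------------

def _mixture_pearson_oracle(spec, ma, mb):
    """Closed-form pooled Pearson correlation induced by group mixing alone
    (zero within-group correlation) for two normal marginals."""
    p = spec.proportion_patients
    ca, cb = spec.marginals["CAD"][ma], spec.marginals["CAD"][mb]
    na, nb = spec.marginals["control"][ma], spec.marginals["control"][mb]
    dmu1, dmu2 = ca.mean - na.mean, cb.mean - nb.mean
    v1 = p * ca.sd ** 2 + (1 - p) * na.sd ** 2
    v2 = p * cb.sd ** 2 + (1 - p) * nb.sd ** 2
    q = p * (1 - p)
    return q * dmu1 * dmu2 / math.sqrt((v1 + q * dmu1 ** 2) * (v2 + q * dmu2 ** 2))


class TestCopulaCalibration:
    def test_mixture_only_pooled_pearson_matches_closed_form(self):
        """With zero within-group correlation, the pooled Pearson
        correlation is produced entirely by the group-mean separation and
        must match the two-component mixture covariance formula (~0.39 for
        the 4D-cf pair)."""
        spec = default_cohort_spec(n_cad=33000, n_control=17000)
        oracle = _mixture_pearson_oracle(spec, "pwv_4d", "cf_pwv")
        assert oracle == pytest.approx(0.39, abs=0.01)
        cohort = draw_cohort(spec, seed=11)
        x = np.array([s.drawn["pwv_4d"] for s in cohort])
        y = np.array([s.drawn["cf_pwv"] for s in cohort])
        assert pearsonr(x, y).statistic == pytest.approx(oracle, abs=0.02)

    def test_calibrated_pair_reaches_target_on_fresh_draws(self):
        spec = default_cohort_spec()
        mat = calibrate_copula(spec, {("pwv_4d", "cf_pwv"): 0.66},
                               n_mc=20000, tol=0.01, seed=0)
        spec.copula = mat
        i, j = MEASURES.index("pwv_4d"), MEASURES.index("cf_pwv")
        assert mat[i, j] > 0.2
        big = default_cohort_spec(n_cad=33000, n_control=17000,
                                  copula=mat)
        cohort = draw_cohort(big, seed=123)
        x = np.array([s.drawn["pwv_4d"] for s in cohort])
        y = np.array([s.drawn["cf_pwv"] for s in cohort])
        assert spearmanr(x, y).statistic == pytest.approx(0.66, abs=0.02)

    def test_mixture_only_target_calibrates_to_zero(self):
        """Asking for exactly the pooled correlation that group mixing
        already produces must return a within-group correlation near 0."""
        spec = default_cohort_spec()
        from aortastiff.synthetic import _pooled_spearman_mc
        from numpy.random import default_rng
        zbase = default_rng(99).standard_normal((40000, 2))
        n_cad = int(round(40000 * spec.proportion_patients))
        f0 = _pooled_spearman_mc(0.0, zbase, n_cad,
                                 (spec.marginals["CAD"]["pwv_4d"],
                                  spec.marginals["CAD"]["cf_pwv"]),
                                 (spec.marginals["control"]["pwv_4d"],
                                  spec.marginals["control"]["cf_pwv"]))
        mat = calibrate_copula(spec, {("pwv_4d", "cf_pwv"): f0},
                               n_mc=20000, tol=0.005, seed=1)
        i, j = MEASURES.index("pwv_4d"), MEASURES.index("cf_pwv")
        assert abs(mat[i, j]) < 0.08

    def test_monotonicity_of_pooled_spearman(self):
        from aortastiff.synthetic import _pooled_spearman_mc
        from numpy.random import default_rng
        spec = default_cohort_spec()
        zbase = default_rng(5).standard_normal((20000, 2))
        args = (zbase, int(20000 * spec.proportion_patients),
                (spec.marginals["CAD"]["pwv_4d"],
                 spec.marginals["CAD"]["cf_pwv"]),
                (spec.marginals["control"]["pwv_4d"],
                 spec.marginals["control"]["cf_pwv"]))
        vals = [_pooled_spearman_mc(r, *args)
                for r in (-0.9, -0.5, 0.0, 0.5, 0.9)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_unreachable_target_reports_attainable_range(self):
        spec = default_cohort_spec()
        with pytest.raises(CalibrationError) as exc:
            calibrate_copula(spec, {("pwv_4d", "distensibility"): 0.95},
                             n_mc=10000, seed=0)
        assert exc.value.attainable is not None
        lo, hi = exc.value.attainable
        assert lo < hi < 0.95


class TestMarginals:
    def test_lognormal_median_iqr_roundtrip(self):
        m = LogNormalMarginal.from_median_iqr(1.71, 1.19, 2.17)
        assert m.median == pytest.approx(1.71)
        q25, q75 = m.ppf(0.25), m.ppf(0.75)
        assert q75 - q25 == pytest.approx(2.17 - 1.19, rel=1e-9)

    def test_invalid_marginals_rejected(self):
        with pytest.raises(InvalidArgumentError):
            NormalMarginal(10.0, -1.0)
        with pytest.raises(InvalidArgumentError):
            LogNormalMarginal.from_median_iqr(1.0, 1.5, 2.0)
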