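"""Waveform metrics, the renormalising fitness and signal conditioning."""

import numpy as np
import pytest

from cardiofit.cellmodel import TOY_BASELINE_PARAMS, toy_ap
from cardiofit.waveform import (
    APTrace, BaselineSet, PENALTY_RMSE, add_noise, align_half_max,
    biomarkers, ensemble_average, fitness, lsq_rescale, notch_60hz, rmse,
)


def _shifted(trace, delay_ms):
    """Same waveform, upstroke delayed by an integer number of samples."""
    n = int(round(delay_ms / trace.dt))
    v = np.concatenate([np.full(n, trace.v[0]), trace.v[:-n]])
    return APTrace(trace.time, v, trace.pcl)


class TestAlignment:
    def test_self_alignment_zero_shift(self):
        tr = toy_ap(TOY_BASELINE_PARAMS, 500.0)
        assert align_half_max(tr, tr).shift == pytest.approx(0.0, abs=1e-9)

    def test_constructed_delay_recovered(self):
        tr = toy_ap(TOY_BASELINE_PARAMS, 500.0)
        res = align_half_max(tr, _shifted(tr, 7.0))
        assert res.shift == pytest.approx(-7.0, abs=0.05)
        # aligned candidate superimposes the reference on the overlap
        assert np.max(np.abs(res.v_ref - res.v_cand)) < 1.0

    def test_noisy_shift_recovered_within_half_ms(self):
        tr = toy_ap(TOY_BASELINE_PARAMS, 500.0)
        delayed = add_noise(_shifted(tr, 13.0), 28.0, seed=7)
        res = align_half_max(tr, delayed)
        assert res.shift == pytest.approx(-13.0, abs=0.5)

    def test_flat_trace_flags_failure(self):
        flat = APTrace(np.arange(100.0), np.zeros(100), 100.0)
        tr = toy_ap(TOY_BASELINE_PARAMS, 500.0)
        assert not align_half_max(tr, flat).ok


class TestLsqRescale:
    def test_exact_affine_inverted(self):
        model = toy_ap(TOY_BASELINE_PARAMS, 500.0).v
        ref = 2.0 * model + 3.0
        alpha, beta, scaled = lsq_rescale(ref, model)
        assert alpha == pytest.approx(0.5)
        assert beta == pytest.approx(-1.5)
        np.testing.assert_allclose(scaled, model, atol=1e-9)

    def test_identity(self):
        v = toy_ap(TOY_BASELINE_PARAMS, 500.0).v
        alpha, beta, _ = lsq_rescale(v, v)
        assert alpha == pytest.approx(1.0)
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_matches_refined_grid_search(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=100)
        cand = 1.7 * ref - 4.0 + rng.normal(0, 0.3, size=100)
        alpha, beta, _ = lsq_rescale(ref, cand)
        # independent oracle: iteratively refined 2-D grid search of the SSE
        a_lo, a_hi, b_lo, b_hi = 0.0, 4.0, -8.0, 0.0
        for _ in range(8):
            aa = np.linspace(a_lo, a_hi, 41)
            bb = np.linspace(b_lo, b_hi, 41)
            sse = ((aa[:, None, None] * ref + bb[None, :, None] - cand) ** 2
                   ).sum(axis=2)
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            da, db = aa[1] - aa[0], bb[1] - bb[0]
            a_lo, a_hi = aa[i] - da, aa[i] + da
            b_lo, b_hi = bb[j] - db, bb[j] + db
        assert alpha == pytest.approx(aa[i], abs=1e-6)
        assert beta == pytest.approx(bb[j], abs=1e-6)

    def test_zero_variance_reference_raises(self):
        with pytest.raises(ValueError):
            lsq_rescale(np.ones(50), np.arange(50.0))


class TestRmse:
    def test_identical_zero_and_offset_closed_form(self):
        v = toy_ap(TOY_BASELINE_PARAMS, 500.0).v
        assert rmse(v, v) == 0.0
        assert rmse(v, v + 3.25) == pytest.approx(3.25)

    def test_gaussian_noise_recovers_sigma(self):
        rng = np.random.default_rng(11)
        v = np.zeros(10_000)
        sigma = 6.039
        assert rmse(v, v + rng.normal(0, sigma, v.size)) == pytest.approx(
            sigma, rel=0.05)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(5), np.zeros(6))


class TestFitness:
    def _baselines(self, mode="absolute"):
        traces = {p: toy_ap(TOY_BASELINE_PARAMS, p)
                  for p in (300.0, 1000.0)}
        return BaselineSet(traces=traces, mode=mode)

    def test_perfect_candidate_scores_zero(self):
        bl = self._baselines()
        total, per = fitness(bl, dict(bl.traces))
        assert total == 0.0
        assert all(v == 0.0 for v in per.values())

    def test_subthreshold_amplitude_draws_penalty(self):
        bl = self._baselines()
        cands = dict(bl.traces)
        t = cands[300.0]
        cands[300.0] = APTrace(t.time, t.v * 0.2 - 60.0, 300.0)  # 25 mV amp
        total, _ = fitness(bl, cands)
        assert total == PENALTY_RMSE

    def test_integration_failure_draws_penalty(self):
        bl = self._baselines()
        cands = dict(bl.traces)
        cands[1000.0] = None
        total, per = fitness(bl, cands)
        assert total == PENALTY_RMSE
        assert per[1000.0] == PENALTY_RMSE

    def test_weighted_sum_not_normalised(self):
        bl = self._baselines()
        cands = {p: APTrace(t.time, t.v + {300.0: 2.0, 1000.0: 4.0}[p], p)
                 for p, t in bl.traces.items()}
        total, per = fitness(bl, cands)
        assert per[300.0] == pytest.approx(2.0)
        assert per[1000.0] == pytest.approx(4.0)
        assert total == pytest.approx(6.0)

    def test_optical_mode_invariant_to_affine_and_shift(self):
        traces = {p: toy_ap(TOY_BASELINE_PARAMS, p)
                  for p in (500.0, 1000.0)}
        bl_plain = BaselineSet(traces=traces, mode="optical")
        cands = {p: toy_ap(TOY_BASELINE_PARAMS * [1.0, 1.0, 1.1, 1.0], p)
                 for p in traces}
        base_total, _ = fitness(bl_plain, cands)
        rng = np.random.default_rng(5)
        for _ in range(3):
            a = rng.uniform(0.2, 3.0)
            b = rng.uniform(-50, 50)
            shift = rng.integers(1, 20)
            warped = {}
            for p, t in traces.items():
                d = _shifted(t, float(shift))
                warped[p] = APTrace(d.time, a * d.v + b, p, normalized=True)
            total, _ = fitness(BaselineSet(traces=warped, mode="optical"),
                               cands)
            assert total == pytest.approx(base_total, rel=0.02, abs=0.05)

    def test_optical_identical_shapes_score_near_zero(self):
        traces = {p: toy_ap(TOY_BASELINE_PARAMS, p) for p in (500.0,)}
        bl = BaselineSet(traces={
            p: APTrace(t.time, (t.v - t.v.min()) / np.ptp(t.v), p, True)
            for p, t in traces.items()}, mode="optical")
        total, _ = fitness(bl, traces)
        assert total < 0.1


class TestBiomarkers:
    def test_square_pulse_apd(self):
        t = np.arange(500.0)
        v = np.where((t >= 50) & (t < 150), 20.0, -85.0)
        bm = biomarkers(APTrace(t, v, 500.0), level=0.8)
        assert bm["APD"] == pytest.approx(100.0, abs=2.0)
        assert bm["RMP"] == pytest.approx(-85.0)
        assert bm["amplitude"] == pytest.approx(105.0)

    def test_affine_rescaling_leaves_apd_unchanged(self):
        tr = toy_ap(TOY_BASELINE_PARAMS, 1000.0)
        a1 = biomarkers(tr, level=0.8)["APD"]
        tr2 = APTrace(tr.time, 0.008 * tr.v + 0.7, 1000.0, normalized=True)
        a2 = biomarkers(tr2, level=0.8)["APD"]
        assert a2 == pytest.approx(a1, abs=0.01)

    def test_no_repolarisation_flags_undefined(self):
        t = np.arange(300.0)
        v = np.where(t > 50, 20.0, -85.0)   # never repolarises
        bm = biomarkers(APTrace(t, v, 300.0), level=0.8)
        assert bm["APD"] is None


class TestNoise:
    def test_infinite_snr_is_identity(self):
        tr = toy_ap(TOY_BASELINE_PARAMS, 500.0)
        out = add_noise(tr, np.inf, seed=0)
        np.testing.assert_array_equal(out.v, tr.v)

    def test_empirical_snr_matches_request(self):
        rng = np.random.default_rng(0)
        t = np.arange(10_000.0)
        v = 50.0 * np.sin(2 * np.pi * t / 400.0)
        tr = APTrace(t, v, 10_000.0)
        for snr in (28.0, 20.0):
            noisy = add_noise(tr, snr, seed=1)
            p_sig = np.mean((v - v.mean()) ** 2)
            p_noise = np.mean((noisy.v - v) ** 2)
            measured = 10.0 * np.log10(p_sig / p_noise)
            assert measured == pytest.approx(snr, abs=0.5)

    def test_sigma_ratio_between_28_and_20_db(self):
        tr = toy_ap(TOY_BASELINE_PARAMS, 1000.0)
        n28 = add_noise(tr, 28.0, seed=2).v - tr.v
        n20 = add_noise(tr, 20.0, seed=2).v - tr.v
        ratio = np.std(n20) / np.std(n28)
        assert ratio == pytest.approx(10 ** (8.0 / 20.0), rel=0.05)


class TestFilters:
    def test_notch_removes_60hz_tone(self):
        t = np.arange(2000.0)    # ms at 1 kHz
        hum = 5.0 * np.sin(2 * np.pi * 60.0 * t / 1000.0)
        tr = APTrace(t, hum, 2000.0)
        out = notch_60hz(tr)
        assert np.max(np.abs(out.v[200:-200])) < 0.05 * 5.0

    def test_notch_requires_sufficient_sampling(self):
        t = np.arange(0.0, 1000.0, 10.0)    # 100 Hz
        with pytest.raises(ValueError):
            notch_60hz(APTrace(t, np.zeros(t.size), 1000.0))

    def test_ensemble_of_identical_traces_is_identity(self):
        tr = toy_ap(TOY_BASELINE_PARAMS, 500.0)
        out = ensemble_average([tr, tr.copy(), tr.copy()])
        np.testing.assert_allclose(out.v, tr.v, atol=1e-12)

    def test_ensemble_averaging_improves_snr(self):
        tr = toy_ap(TOY_BASELINE_PARAMS, 500.0)
        n = 8
        noisy = [add_noise(tr, 20.0, seed=100 + i) for i in range(n)]
        avg = ensemble_average(noisy)
        sel = slice(0, avg.v.size)
        p_sig = np.mean((tr.v - tr.v.mean()) ** 2)
        p_before = np.mean((noisy[0].v - tr.v) ** 2)
        p_after = np.mean((avg.v - tr.v[sel]) ** 2)
        gain = 10 * np.log10(p_before / p_after)
        assert gain == pytest.approx(10 * np.log10(n), abs=2.0)

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            ensemble_average([])
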