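"""Record synthesis: MVN coupling, HRV, beat assembly, noise, filtering."""

import math

import numpy as np
import pytest
from scipy import signal as sps

from ecgforge import (BeatECG12, HRVParams, MVNSpec, NoiseModel, add_noise,
                      assemble_record, bandpass_filter, concat_beat,
                      generate_rr_series, sample_pq, scale_qrst, stretch_beat)
from ecgforge.config import SynthesisConfig
from ecgforge.synthesis import butterworth_sos


@pytest.fixture(scope="module")
def mvn():
    return MVNSpec.default()


def toy_beat(fs=500.0):
    """A stylized full beat with known fiducials."""
    t = np.arange(0, 500.0, 1000.0 / fs)
    x = np.zeros_like(t)
    # P wave
    x += 0.1 * np.exp(-0.5 * ((t - 60) / 18) ** 2)
    # QRS
    x += 1.0 * np.exp(-0.5 * ((t - 170) / 8) ** 2)
    # T wave
    x += 0.3 * np.exp(-0.5 * ((t - 340) / 35) ** 2)
    data = np.tile(x, (12, 1))
    fid = {"P_on": 20.0, "P_off": 100.0, "QRS_on": 140.0,
           "QRS_off": 200.0, "T_off": 420.0}
    return BeatECG12(data=data, fs=fs, fiducials=fid)


class TestMVN:
    def test_conditional_matches_closed_form_monte_carlo(self, mvn):
        """Empirical conditional moments over 10^4 draws agree with the
        analytic Gaussian conditioning."""
        rng = np.random.default_rng(0)
        names, mu_c, cov_c = mvn.conditional("rate", {"RR_int": 1000.0})
        draws = rng.multivariate_normal(mu_c, cov_c, size=10000)
        se = np.sqrt(np.diag(cov_c) / 10000)
        assert np.all(np.abs(draws.mean(axis=0) - mu_c) < 4 * se)
        assert np.allclose(np.cov(draws.T), cov_c, rtol=0.1)

    def test_conditioning_at_the_mean_returns_the_mean(self, mvn):
        names, mu, cov = mvn.blocks["amplitude"]
        _, mu_c, _ = mvn.conditional("amplitude", {"P_amp": mu[0]})
        assert mu_c[0] == pytest.approx(mu[1])

    def test_zero_correlation_reduces_to_marginal(self):
        cfg = SynthesisConfig(corr_amp=0.0)
        spec = MVNSpec.default(cfg)
        names, mu, cov = spec.blocks["amplitude"]
        _, mu_c, cov_c = spec.conditional("amplitude", {"P_amp": 0.2})
        assert mu_c[0] == pytest.approx(mu[1])
        assert cov_c[0, 0] == pytest.approx(cov[1, 1])

    def test_fit_from_feature_table_roundtrip(self, mvn):
        import pandas as pd
        rng = np.random.default_rng(1)
        cols = ("P_amp", "R_amp", "P_dur", "PQ_int", "QRS_dur", "QT_int",
                "RR_int")
        names, mu, cov = mvn.blocks["rate"]
        rows = rng.multivariate_normal(mu, cov, size=4000)
        df = pd.DataFrame({c: rng.normal(100, 10, 4000) for c in cols})
        for i, n in enumerate(names):
            df[n] = rows[:, i]
        fit = MVNSpec.from_feature_table(df)
        assert np.allclose(fit.blocks["rate"][1], mu, rtol=0.02)
        assert np.allclose(fit.blocks["rate"][2], cov, rtol=0.2, atol=50.0)


class TestScaleAndPQ:
    def test_scaled_r_peak_matches_target_mechanism(self, mvn):
        beat = toy_beat()
        pw = BeatECG12(data=beat.data * 0.1, fs=500.0,
                       fiducials={"P_on": 20.0, "P_off": 100.0})
        rng = np.random.default_rng(5)
        out = scale_qrst(beat, pw, mvn, rng)
        # one global factor: all leads scaled identically
        ratio = out.data / beat.data
        assert np.allclose(ratio, ratio[0, 0])
        assert out.fiducials == beat.fiducials

    def test_nonpositive_p_amplitude_rejected(self, mvn):
        beat = toy_beat()
        flat = BeatECG12(data=np.zeros_like(beat.data), fs=500.0,
                         fiducials={"P_on": 0.0, "P_off": 100.0})
        with pytest.raises(ValueError):
            scale_qrst(beat, flat, mvn, np.random.default_rng(0))

    def test_avb_pq_always_above_200(self, mvn):
        rng = np.random.default_rng(2)
        draws = [sample_pq(90.0, mvn, avb=True, rng=rng)
                 for _ in range(1000)]
        assert min(draws) > 200.0

    def test_pq_respects_p_duration(self, mvn):
        rng = np.random.default_rng(3)
        draws = [sample_pq(170.0, mvn, avb=False, rng=rng)
                 for _ in range(500)]
        assert min(draws) >= 170.0

    def test_pq_conditional_mean_matches_oracle(self, mvn):
        """The empirical mean matches the closed-form conditional
        Gaussian truncated at PQ >= P_dur, within Monte-Carlo error."""
        from scipy.stats import truncnorm
        rng = np.random.default_rng(4)
        p_dur = 140.0
        _, mu_c, cov_c = mvn.conditional("conduction", {"P_dur": p_dur})
        sd = math.sqrt(cov_c[0, 0])
        a = (p_dur - mu_c[0]) / sd
        expected = truncnorm.mean(a, np.inf, loc=mu_c[0], scale=sd)
        draws = np.array([sample_pq(p_dur, mvn, avb=False, rng=rng)
                          for _ in range(4000)])
        se = sd / math.sqrt(4000)
        assert abs(draws.mean() - expected) < 5 * se


class TestConcat:
    def make_parts(self):
        pw = toy_beat()
        pw = BeatECG12(data=pw.data[:, :60] * 0.1, fs=500.0,
                       fiducials={"P_on": 0.0, "P_off": 95.0})
        q = toy_beat()
        q.fiducials = {"QRS_on": 140.0, "QRS_off": 200.0, "T_off": 420.0}
        return pw, q

    def test_degenerate_connector(self):
        pw, q = self.make_parts()
        beat = concat_beat(pw, q, pq=95.0)
        assert beat.fiducials["QRS_on"] == 95.0
        n_p = int(round(95.0 / 2.0))
        assert np.allclose(beat.data[:, :n_p], pw.data[:, :n_p])

    def test_junction_continuity(self):
        pw, q = self.make_parts()
        beat = concat_beat(pw, q, pq=160.0)
        jumps = np.abs(np.diff(beat.data, axis=1))
        n_p = int(round(95.0 / 2.0))
        n_c = int(round(160.0 / 2.0)) - n_p
        junctions = jumps[:, [n_p - 1, n_p + n_c - 1]]
        assert junctions.max() <= jumps.max()

    def test_connector_endpoints_exact(self):
        pw, q = self.make_parts()
        beat = concat_beat(pw, q, pq=180.0)
        n_p = int(round(95.0 / 2.0))
        i_q = int(round(140.0 / 2.0))
        n_c = int(round(180.0 / 2.0)) - n_p
        # connector first/last samples interpolate between the joined
        # segment boundary amplitudes
        left = pw.data[:, n_p - 1]
        right = q.data[:, i_q]
        conn = beat.data[:, n_p:n_p + n_c]
        assert np.all((conn.min(axis=1) >= np.minimum(left, right) - 1e-12)
                      & (conn.max(axis=1) <= np.maximum(left, right)
                         + 1e-12))

    def test_pq_shorter_than_p_rejected(self):
        pw, q = self.make_parts()
        with pytest.raises(ValueError):
            concat_beat(pw, q, pq=60.0)


class TestHRV:
    def test_zero_sdnn_constant_series(self):
        rr = generate_rr_series(HRVParams(mean_hr=60.0, sdnn=0.0,
                                          n_beats=12, seed=0))
        assert np.allclose(rr, 1000.0)

    def test_mean_rr_in_physiological_range(self):
        for hr in (50.0, 70.0, 90.0):
            rr = generate_rr_series(HRVParams(mean_hr=hr, sdnn=30.0,
                                              n_beats=64, seed=1))
            assert 666.0 <= 60000.0 / hr <= 1200.0
            assert abs(rr.mean() - 60000.0 / hr) < 40.0

    def test_spectral_exponent(self):
        """Periodogram log-log slope ~ -beta on a long series."""
        n = 2 ** 14
        rr = generate_rr_series(HRVParams(mean_hr=70.0, sdnn=40.0,
                                          n_beats=n, seed=7,
                                          spectral_exponent=1.0))
        f, p = sps.periodogram(rr - rr.mean())
        sel = (f > 1e-3) & (f < 0.4)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.3)

    def test_heart_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            HRVParams(mean_hr=120.0)


class TestStretch:
    def test_qrs_untouched_by_warp(self, mvn):
        beat = toy_beat()
        rng = np.random.default_rng(8)
        out = stretch_beat(beat, 900.0, mvn, rng)
        assert out.fiducials["QRS_on"] == beat.fiducials["QRS_on"]
        assert out.fiducials["QRS_off"] == beat.fiducials["QRS_off"]
        i_off = int(round(beat.fiducials["QRS_off"] / 2.0))
        assert np.array_equal(out.data[:, :i_off], beat.data[:, :i_off])

    def test_qt_increases_with_rr_on_average(self, mvn):
        beat = toy_beat()
        rng = np.random.default_rng(9)
        qts = {rr: np.mean([stretch_beat(beat, rr, mvn, np.random.default_rng(
            1000 + k)).fiducials["T_off"]
            - beat.fiducials["QRS_on"] for k in range(200)])
            for rr in (700.0, 1100.0)}
        assert qts[1100.0] > qts[700.0]


class TestAssembleNoiseFilter:
    def make_record(self):
        beat = toy_beat()
        rr = np.full(22, 520.0)
        return assemble_record([beat] * 22, rr)

    def test_output_shape_and_beat_count(self):
        data, fids = self.make_record()
        assert data.shape == (12, 5000)
        assert len(fids) == 20   # beats with onset inside the window
        # fiducial ordering per beat, increasing across beats
        prev = -1.0
        for f in fids:
            assert f["P_on"] < f["P_off"] <= f["QRS_on"] < f["QRS_off"] \
                < f["T_off"]
            assert f["P_on"] > prev
            prev = f["P_on"]

    def test_beat_exceeding_slot_rejected(self):
        beat = toy_beat()
        with pytest.raises(ValueError, match="slot"):
            assemble_record([beat] * 30, np.full(30, 400.0))

    def test_snr_scaling_exact(self):
        data, _ = self.make_record()
        noisy = add_noise(data, NoiseModel(snr_db=15.0, seed=3))
        noise = noisy - data
        snr = 10 * np.log10(np.mean(data**2) / np.mean(noise**2))
        assert snr == pytest.approx(15.0, abs=0.1)

    def test_infinite_snr_returns_input(self):
        data, _ = self.make_record()
        noisy = add_noise(data, NoiseModel(snr_db=np.inf, seed=3))
        assert np.array_equal(noisy, data)

    def test_noise_deterministic_in_seed(self):
        data, _ = self.make_record()
        n1 = add_noise(data, NoiseModel(snr_db=18.0, seed=9))
        n2 = add_noise(data, NoiseModel(snr_db=18.0, seed=9))
        assert np.array_equal(n1, n2)

    def test_noise_preserves_lead_identities(self, sinus_records):
        r = sinus_records[0]
        for arr in (r.noisy, r.filtered):
            assert np.abs(arr[0] - arr[1] + arr[2]).max() < 1e-9
            assert np.abs(arr[3] + arr[4] + arr[5]).max() < 1e-9

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros((12, 5000)), NoiseModel(snr_db=15.0))

    def test_filter_rejects_dc(self):
        x = np.ones((12, 5000))
        y = bandpass_filter(x)
        assert np.abs(y.mean(axis=1)).max() < 0.01

    def test_filter_preserves_10hz(self):
        t = np.arange(5000) / 500.0
        x = np.sin(2 * np.pi * 10.0 * t)[None, :] * np.ones((12, 1))
        y = bandpass_filter(x)
        mid = slice(1000, 4000)
        amp = math.sqrt(2.0) * np.sqrt(np.mean(y[0, mid] ** 2))
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_highpass_prototype_minus_3db_at_cutoff(self):
        hp, _ = butterworth_sos()
        w, h = sps.sosfreqz(hp, worN=[0.5], fs=500.0)
        gain_db = 20 * np.log10(np.abs(h[0]))
        assert gain_db == pytest.approx(-3.0, abs=0.2)


class TestRecordLevel:
    def test_determinism_end_to_end(self, sinus_records, anatomies,
                                    shared_cache):
        from ecgforge import PathologyLabel, generate_records
        again = []
        gen = generate_records(PathologyLabel("sinus"), 8, 2024,
                               anatomies=anatomies, cache=shared_cache)
        for _ in range(2):
            again.append(next(gen)[2])
        for a, b in zip(sinus_records[:2], again):
            assert np.array_equal(a.raw, b.raw)
            assert np.array_equal(a.noisy, b.noisy)
            assert np.array_equal(a.filtered, b.filtered)

    def test_fiducials_consistent(self, sinus_records):
        for rec in sinus_records:
            prev_end = -1.0
            for f in rec.fiducials:
                assert f["P_on"] < f["P_off"] <= f["QRS_on"] \
                    < f["QRS_off"] < f["T_off"]
                assert f["P_on"] > prev_end
                prev_end = f["P_on"]

    def test_delineated_mean_rr_matches_generator(self, sinus_records):
        from ecgforge import delineate
        for rec in sinus_records[:3]:
            fs = delineate(rec.raw[1], rec.fs)
            det_rr = np.diff(fs.series("r_peak")).mean()
            gt_rr = np.diff([f["QRS_on"] for f in rec.fiducials]).mean()
            assert det_rr == pytest.approx(gt_rr, rel=0.02)
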