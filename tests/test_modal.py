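"""Oscillation-detector tests: PSD, background fit, bands, traces, gating."""

import numpy as np
import pytest

from hippotheta import modal
from hippotheta.synthdata import ElectrodeSpec, SimConfig, colored_noise, simulate_ieeg
from hippotheta.types import Band, PowerSpectrum


def analytic_power_law(exponent=-2.0, lo=1.0, hi=30.0, n=291):
    f = np.linspace(lo, hi, n)
    return PowerSpectrum(f, f**exponent)


def gaussian_bump(freqs, center, height, sigma=0.5):
    return height * np.exp(-0.5 * ((freqs - center) / sigma) ** 2)


class TestComputePsd:
    def test_sine_peak_location(self, rng):
        fs = 1000.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 8 * t) + 0.01 * rng.standard_normal(t.size)
        psd = modal.compute_psd(x, fs)
        sel = (psd.frequencies >= 2) & (psd.frequencies <= 14)
        peak = psd.frequencies[sel][np.argmax(psd.power[sel])]
        assert peak == pytest.approx(8.0, abs=0.25)

    def test_white_noise_is_flat(self, rng):
        x = rng.standard_normal(200_000)
        psd = modal.compute_psd(x, 1000.0)
        sel = (psd.frequencies >= 2) & (psd.frequencies <= 30)
        slope = np.polyfit(np.log10(psd.frequencies[sel]),
                           np.log10(psd.power[sel]), 1)[0]
        assert slope == pytest.approx(0.0, abs=0.15)

    def test_shaped_noise_slope(self):
        x = colored_noise(200_000, 1000.0, 2.0, np.random.default_rng(5))
        psd = modal.compute_psd(x, 1000.0)
        fit = modal.fit_background(psd)
        assert fit.slope == pytest.approx(-2.0, abs=0.2)

    def test_masked_samples_are_ignored(self, rng):
        fs = 1000.0
        t = np.arange(0, 120, 1 / fs)
        x = 0.1 * rng.standard_normal(t.size)
        # a huge 5 Hz artifact in a masked stretch must not reach the PSD
        mask = np.zeros(t.size, dtype=bool)
        mask[: 30 * 1000] = True
        x[mask] += 50 * np.sin(2 * np.pi * 5 * t[mask])
        psd = modal.compute_psd(x, fs, mask)
        sel = (psd.frequencies >= 4.5) & (psd.frequencies <= 5.5)
        other = (psd.frequencies >= 10) & (psd.frequencies <= 11)
        assert psd.power[sel].mean() < 10 * psd.power[other].mean()

    def test_too_little_unmasked_data(self, rng):
        x = rng.standard_normal(20_000)
        mask = np.ones(20_000, dtype=bool)
        mask[:5000] = False
        with pytest.raises(ValueError, match="10 s"):
            modal.compute_psd(x, 1000.0, mask)


class TestFitBackground:
    def test_exact_power_law(self):
        fit = modal.fit_background(analytic_power_law(-2.0))
        assert fit.slope == pytest.approx(-2.0, abs=0.01)
        assert fit.residual_sd < 1e-6

    def test_exact_flat_spectrum(self):
        fit = modal.fit_background(analytic_power_law(0.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_bump_does_not_bias_slope(self):
        f = np.linspace(1, 30, 291)
        base = f**-2.0
        p = base + gaussian_bump(f, 8.0, 10 * base[np.argmin(abs(f - 8))])
        fit = modal.fit_background(PowerSpectrum(f, p))
        assert fit.slope == pytest.approx(-2.0, abs=0.1)

    def test_nonpositive_power_rejected(self):
        f = np.linspace(1, 30, 291)
        p = f**-2.0
        p[100] = 0.0
        with pytest.raises(ValueError, match="power"):
            modal.fit_background(PowerSpectrum(f, p))


class TestDetectBands:
    def test_pure_power_law_no_bands(self):
        psd = analytic_power_law(-2.0)
        fit = modal.fit_background(psd)
        assert modal.detect_bands(psd, fit) == []

    def test_single_bump_single_band(self):
        f = np.linspace(1, 30, 291)
        base = f**-2.0
        p = base + gaussian_bump(f, 8.0, 10 * base[np.argmin(abs(f - 8))])
        psd = PowerSpectrum(f, p)
        fit = modal.fit_background(psd)
        bands = modal.detect_bands(psd, fit)
        assert len(bands) == 1
        assert bands[0].f_lo <= 8.0 <= bands[0].f_hi

    def test_two_bumps_two_bands(self):
        f = np.linspace(1, 30, 291)
        base = f**-2.0
        p = (base
             + gaussian_bump(f, 3.0, 10 * base[np.argmin(abs(f - 3))])
             + gaussian_bump(f, 8.0, 10 * base[np.argmin(abs(f - 8))]))
        psd = PowerSpectrum(f, p)
        fit = modal.fit_background(psd)
        bands = modal.detect_bands(psd, fit)
        assert len(bands) == 2
        assert bands[0].f_lo <= 3.0 <= bands[0].f_hi
        assert bands[1].f_lo <= 8.0 <= bands[1].f_hi

    def test_matches_brute_force_threshold_scan(self, rng):
        # oracle: enumerate supra-threshold runs point by point
        for _ in range(25):
            f = np.linspace(1, 30, 150)
            logp = -2.0 * np.log10(f) + rng.normal(0, 0.3, f.size)
            psd = PowerSpectrum(f, 10.0**logp)
            fit = modal.fit_background(psd)
            bands = modal.detect_bands(psd, fit, min_points=2, merge_gap_hz=0.5)

            thr = fit.predict_log10(f) + fit.residual_sd
            sel = (f >= 2) & (f <= 14)
            above = (logp > thr) & sel
            runs, cur = [], []
            for i in range(f.size):
                if above[i]:
                    cur.append(i)
                elif cur:
                    runs.append(cur)
                    cur = []
            if cur:
                runs.append(cur)
            runs = [r for r in runs if len(r) >= 2]
            merged = []
            for r in runs:
                if merged and f[r[0]] - f[merged[-1][-1]] < 0.5:
                    merged[-1] = merged[-1] + r
                else:
                    merged.append(r)
            expected = [
                (f[r[0]], f[r[-1]], f[r[np.argmax(logp[r])]]) for r in merged
            ]
            got = [(b.f_lo, b.f_hi, b.peak_freq) for b in bands]
            assert got == pytest.approx(expected)


class TestInstantaneousTrace:
    def test_sine_frequency_and_phase_rate(self):
        fs = 1000.0
        t = np.arange(0, 30, 1 / fs)
        x = np.sin(2 * np.pi * 8 * t)
        tr = modal.instantaneous_trace(x, Band(7.0, 9.0, 8.0), fs)
        inner = slice(2000, -2000)
        assert np.allclose(tr.inst_freq[inner], 8.0, atol=0.05)
        adv = np.unwrap(tr.phase[inner])
        rate = (adv[-1] - adv[0]) / (len(adv) / fs)
        assert rate == pytest.approx(2 * np.pi * 8, rel=0.01)

    def test_chirp_presence_follows_frequency_law(self):
        # f(t) = 5 + 0.1 t over 60 s crosses [7, 9] during t in [20, 40]
        fs = 1000.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * (5 * t + 0.05 * t**2))
        tr = modal.instantaneous_trace(x, Band(7.0, 9.0, 8.0), fs)
        eligible = tr.presence.copy()
        eligible[: 2 * int(fs)] = False  # filter edge transients
        eligible[-2 * int(fs):] = False
        t_in = t[eligible]
        f_at = 5 + 0.1 * t_in
        assert np.all(f_at >= 7 - 0.2) and np.all(f_at <= 9 + 0.2)
        strict = (5 + 0.1 * t >= 7.2) & (5 + 0.1 * t <= 8.8)
        assert eligible[strict].mean() > 0.95

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            modal.instantaneous_trace(np.zeros(1000), Band(7.0, 9.0, 8.0), 1000.0)

    def test_presence_implies_freq_in_band(self, rng):
        x = rng.standard_normal(60_000)
        tr = modal.instantaneous_trace(x, Band(4.0, 6.0, 5.0), 1000.0)
        assert np.all(tr.inst_freq[tr.presence] >= 4.0)
        assert np.all(tr.inst_freq[tr.presence] <= 6.0)


class TestGating:
    def test_constant_sine_stays_present(self, rng):
        fs = 1000.0
        t = np.arange(0, 100, 1 / fs)
        x = np.sin(2 * np.pi * 8 * t) + 0.3 * colored_noise(
            t.size, fs, 2.0, np.random.default_rng(0)
        )
        psd = modal.compute_psd(x, fs)
        fit = modal.fit_background(psd)
        band = Band(7.0, 9.0, 8.0)
        tr = modal.instantaneous_trace(x, band, fs)
        gated = modal.gate_presence(tr, x, fit)
        assert gated.presence.mean() >= 0.95

    def test_localized_oscillation_gates_to_its_window(self):
        fs = 1000.0
        n = 100_000
        x = colored_noise(n, fs, 2.0, np.random.default_rng(1))
        t = np.arange(10_000) / fs
        x[:10_000] += 2.0 * np.sin(2 * np.pi * 8 * t)
        psd = modal.compute_psd(x, fs)
        fit = modal.fit_background(psd)
        band = Band(7.0, 9.0, 8.0)
        tr = modal.instantaneous_trace(x, band, fs)
        gated = modal.gate_presence(tr, x, fit)
        present_idx = np.flatnonzero(gated.presence)
        assert present_idx.size > 0
        assert (present_idx < 10_000).mean() >= 0.95

    def test_noise_less_present_than_sine(self):
        fs = 1000.0
        n = 100_000
        noise = colored_noise(n, fs, 2.0, np.random.default_rng(2))
        t = np.arange(n) / fs
        sine = noise + 2.0 * np.sin(2 * np.pi * 8 * t)
        band = Band(7.0, 9.0, 8.0)
        fracs = []
        for x in (sine, noise):
            psd = modal.compute_psd(x, fs)
            fit = modal.fit_background(psd)
            tr = modal.instantaneous_trace(x, band, fs)
            fracs.append(modal.gate_presence(tr, x, fit).presence.mean())
        assert fracs[0] > fracs[1]

    def test_masked_samples_never_present(self):
        fs = 1000.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 8 * t)
        mask = np.zeros(t.size, dtype=bool)
        mask[10_000:20_000] = True
        psd = modal.compute_psd(x, fs)
        fit = modal.fit_background(psd)
        tr = modal.instantaneous_trace(x, Band(7.0, 9.0, 8.0), fs)
        gated = modal.gate_presence(tr, x, fit, mask=mask)
        assert not gated.presence[10_000:20_000].any()


class TestRecoveryAndMonotonicity:
    @pytest.mark.parametrize("freq", [3.0, 8.0])
    def test_injected_frequency_recovered(self, freq, small_trials, small_config):
        spec = ElectrodeSpec([(freq - 1, freq + 1)], speed_coupled=False)
        rec, _ = simulate_ieeg(spec, small_trials, small_config,
                               np.random.default_rng(int(freq)))
        bands, traces, _ = modal.detect_oscillations(rec.data[0], 1000.0)
        hit = [
            (b, tr) for b, tr in zip(bands, traces) if b.f_lo <= freq <= b.f_hi
        ]
        assert hit
        band, tr = hit[0]
        mean_f = tr.inst_freq[tr.presence].mean()
        assert mean_f == pytest.approx(freq, abs=0.5)

    def test_presence_monotone_in_snr(self, small_trials):
        fracs = []
        for snr in (0.5, 2.0, 6.0):
            cfg = SimConfig(n_trials=12, osc_snr=snr, seed=0)
            rec, _ = simulate_ieeg(
                ElectrodeSpec([(7, 9)], False), small_trials, cfg,
                np.random.default_rng(99),  # same noise seed across SNRs
            )
            psd = modal.compute_psd(rec.data[0], 1000.0)
            fit = modal.fit_background(psd)
            tr = modal.instantaneous_trace(rec.data[0], Band(7.0, 9.0, 8.0), 1000.0)
            fracs.append(modal.gate_presence(tr, rec.data[0], fit).presence.mean())
        assert fracs[0] <= fracs[1] <= fracs[2]
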