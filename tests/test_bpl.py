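"""Lateralised beta power: normalisation, sign conventions, slope and
onset estimators, and the synthetic end-to-end properties."""

import numpy as np
import pandas as pd
import pytest

from flankerddm import (GROUP_PARAMS, GeneratorSpec, bandpower_timecourse,
                        bpl_regression, bpl_slope, bpl_threshold,
                        compute_bpl, detect_onset, generate_beta_epochs,
                        generate_task_design, normalize_power, peak_latency,
                        response_locked, simulate_traces)
from flankerddm.bpl_pipeline import SlopeSeries, channel_role_series
from flankerddm.synthetic_data import BetaEpochs


def _epochs(power, hand=None, response_idx=None, sfreq=250.0):
    n, _, t = power.shape
    meta = pd.DataFrame({
        "hand": np.full(n, -1, int) if hand is None else hand,
        "response_idx": np.full(n, t // 2) if response_idx is None
        else response_idx})
    times = (np.arange(t) - t // 2) / sfreq
    return BetaEpochs(power=power, times=times, sfreq=sfreq, metadata=meta)


class TestNormalization:
    def test_contract_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        ep = _epochs(3 + 2 * rng.standard_normal((40, 2, 100)))
        out = normalize_power(ep)
        for ch in range(2):
            assert out.power[:, ch].mean() == pytest.approx(0, abs=1e-12)
            assert out.power[:, ch].std() == pytest.approx(1, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.standard_normal((10, 2, 50))
        a = normalize_power(_epochs(p))
        b = normalize_power(_epochs(p * np.array([10.0, 1.0])[None, :, None]))
        assert np.allclose(a.power, b.power, atol=1e-12)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        ep = _epochs(5 + rng.standard_normal((10, 2, 50)))
        once = normalize_power(ep)
        twice = normalize_power(once)
        assert np.allclose(once.power, twice.power, atol=1e-10)

    def test_zero_variance_names_channel(self):
        p = np.ones((5, 2, 20))
        p[:, 0] += np.random.default_rng(3).standard_normal((5, 20))
        with pytest.raises(ValueError, match="right_hemi"):
            normalize_power(_epochs(p))


class TestComputeBpl:
    def test_identical_channels_give_zero(self):
        rng = np.random.default_rng(4)
        p = rng.standard_normal((8, 1, 30))
        ep = _epochs(np.concatenate([p, p], axis=1))
        assert np.allclose(compute_bpl(ep).values, 0)

    def test_sign_convention_contra_suppression(self):
        """A contralateral channel suppressed by delta yields BPL -delta."""
        base = np.ones((6, 2, 30))
        hand = np.full(6, -1)       # left hand: contralateral = right hemi
        base[:, 1] -= 0.25
        ep = _epochs(base, hand=hand)
        assert np.allclose(compute_bpl(ep).values, -0.25)

    def test_role_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        p = rng.standard_normal((20, 2, 40))
        hand = np.where(rng.random(20) < 0.5, -1, 1)
        ep = _epochs(p, hand=hand)
        swapped = _epochs(p[:, ::-1].copy(), hand=hand)  # relabel roles
        a = compute_bpl(ep).values
        b = compute_bpl(swapped).values
        assert np.allclose(a, -b, atol=1e-12)

    def test_hand_symmetry(self):
        """Left- and right-hand trials with mirrored channel effects give
        identical BPL."""
        t = 50
        sig = np.sin(np.linspace(0, 3, t))
        left = np.stack([[1 + 0.5 * sig, 1 - 0.5 * sig]])   # ipsi, contra
        right = np.stack([[1 - 0.5 * sig, 1 + 0.5 * sig]])
        ep_l = _epochs(left, hand=[-1])
        ep_r = _epochs(right, hand=[1])
        assert np.allclose(compute_bpl(ep_l).values,
                           compute_bpl(ep_r).values)

    def test_unresolved_hand_dropped(self):
        rng = np.random.default_rng(6)
        ep = _epochs(rng.standard_normal((4, 2, 10)), hand=[-1, 0, 1, -1])
        with pytest.warns(UserWarning, match="unresolved hand"):
            out = compute_bpl(ep)
        assert out.values.shape[0] == 3

    def test_channel_role_series_partition(self):
        rng = np.random.default_rng(7)
        p = rng.standard_normal((10, 2, 20))
        hand = np.where(rng.random(10) < 0.5, -1, 1)
        ep = _epochs(p, hand=hand)
        contra = channel_role_series(ep, "contralateral").values
        ipsi = channel_role_series(ep, "ipsilateral").values
        assert np.allclose(contra - ipsi, compute_bpl(ep).values)


class TestThreshold:
    def test_constant_signal(self):
        ep = _epochs(np.zeros((3, 2, 101)))
        ep.power[:, 1] -= 1.0  # contra (left hand) one unit below
        series = response_locked(compute_bpl(ep), -0.1, 0.1)
        assert np.allclose(bpl_threshold(series), -1.0)

    def test_linear_ramp_through_zero(self):
        t = 101
        ramp = np.linspace(-1, 1, t)
        p = np.zeros((2, 2, t))
        p[:, 1] = -ramp  # BPL = contra - ipsi = -ramp - 0... = -ramp
        ep = _epochs(p)
        series = response_locked(compute_bpl(ep), -0.1, 0.1)
        # the window is symmetric around the response sample, where the
        # ramp crosses zero
        assert bpl_threshold(series) == pytest.approx(0.0, abs=1e-9)

    def test_requires_response_locking(self):
        ep = _epochs(np.zeros((2, 2, 50)))
        with pytest.raises(ValueError, match="response-locked"):
            bpl_threshold(compute_bpl(ep))

    def test_truncated_window_trials_dropped(self):
        ep = _epochs(np.zeros((3, 2, 60)), response_idx=[2, 30, 58])
        with pytest.warns(UserWarning, match="truncated"):
            series = response_locked(compute_bpl(ep), -0.1, 0.1)
        assert series.values.shape[0] == 1


class TestSlope:
    def test_linear_signal_exact_everywhere(self):
        sfreq = 250.0
        times = np.arange(200) / sfreq
        vals = 3.0 * times - 1.0
        ss = bpl_slope(vals, times, sfreq)
        assert np.allclose(ss.slopes, 3.0, atol=1e-8)

    def test_quadratic_exact_at_window_centre(self):
        sfreq = 250.0
        times = np.arange(300) / sfreq
        vals = times**2
        ss = bpl_slope(vals, times, sfreq)
        assert np.allclose(ss.slopes[0], 2.0 * ss.times, atol=1e-8)

    def test_flat_then_ramp_transition_width(self):
        sfreq = 250.0
        times = np.arange(400) / sfreq
        vals = np.where(times < 0.8, 0.0, 5.0 * (times - 0.8))
        ss = bpl_slope(vals, times, sfreq)
        early = ss.slopes[0][ss.times < 0.8 - ss.window / 2]
        late = ss.slopes[0][ss.times > 0.8 + ss.window / 2]
        assert np.allclose(early, 0.0, atol=1e-9)
        assert np.allclose(late, 5.0, atol=1e-8)

    def test_window_exceeding_epoch(self):
        with pytest.raises(ValueError):
            bpl_slope(np.zeros(5), np.arange(5) / 250, 250.0)

    def test_role_swap_negates_slopes(self):
        rng = np.random.default_rng(8)
        vals = rng.standard_normal(200)
        times = np.arange(200) / 250
        a = bpl_slope(vals, times, 250.0).slopes
        b = bpl_slope(-vals, times, 250.0).slopes
        assert np.allclose(a, -b, atol=1e-12)


class TestOnsetAndPeak:
    def _slope_series(self, slopes):
        g = slopes.shape[1]
        return SlopeSeries(times=np.arange(g) * 0.04, slopes=slopes,
                           window=0.08, hop=10, sfreq=250.0)

    def test_pure_noise_has_no_onset(self):
        rng = np.random.default_rng(9)
        ss = self._slope_series(rng.standard_normal((10, 30)))
        assert detect_onset(ss) is None

    def test_onset_at_signal_start(self):
        rng = np.random.default_rng(10)
        slopes = 0.05 * rng.standard_normal((12, 30))
        slopes[:, 15:] += 2.0
        ss = self._slope_series(slopes)
        assert detect_onset(ss) == pytest.approx(15 * 0.04)

    def test_more_participants_detect_earlier_on_average(self):
        """Doubling the number of participants at a fixed effect does not
        delay the detected onset on aggregate over seeds (monotone
        power)."""
        onsets = {8: [], 16: []}
        latest = 29 * 0.04
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            big = 0.8 * rng.standard_normal((16, 30))
            big[:, 12:] += np.linspace(0.3, 1.5, 18)
            for n in (8, 16):
                ss = self._slope_series(big[:n])
                o = detect_onset(ss)
                onsets[n].append(latest if o is None else o)
        assert np.mean(onsets[16]) <= np.mean(onsets[8])
        assert np.median(onsets[16]) <= np.median(onsets[8])

    def test_peak_latency_centre_and_shift(self):
        times = np.linspace(-0.4, 0.4, 201)
        bump = -np.exp(-(times**2) / (2 * 0.05**2))
        assert peak_latency(bump, times) == pytest.approx(0.0, abs=1e-9)
        shifted = -np.exp(-((times - 0.02)**2) / (2 * 0.05**2))
        assert peak_latency(shifted, times) == pytest.approx(0.02, abs=0.005)
        assert peak_latency(np.zeros_like(times), times) is None


class TestMorletBandpower:
    def test_amplitude_ratio_in_log_power(self):
        """Doubling the amplitude of an 18 Hz sinusoid shifts the
        band-power plateau by 2 ln 2."""
        sfreq = 500.0
        t = np.arange(int(4.0 * sfreq)) / sfreq
        sig = np.sin(2 * np.pi * 18 * t)
        data = np.stack([np.stack([sig, 2 * sig])])
        beta = bandpower_timecourse(data, sfreq=sfreq)
        mid = slice(beta.power.shape[-1] // 3, 2 * beta.power.shape[-1] // 3)
        diff = beta.power[0, 1, mid] - beta.power[0, 0, mid]
        assert np.allclose(diff, 2 * np.log(2), atol=1e-6)

    def test_white_noise_power_is_flat(self):
        rng = np.random.default_rng(11)
        sfreq = 500.0
        data = rng.standard_normal((100, 2, int(4 * sfreq)))
        beta = bandpower_timecourse(data, sfreq=sfreq)
        mid = beta.power[..., 100:-100].mean(axis=(0, 1))
        # coarse time bins of the trial-averaged log power stay level
        bins = mid[: len(mid) // 8 * 8].reshape(8, -1).mean(axis=1)
        assert np.ptp(bins) < 0.2  # no systematic time course

    def test_passthrough_for_band_power_input(self):
        ep = _epochs(np.ones((2, 2, 10)))
        assert bandpower_timecourse(ep) is ep

    def test_band_outside_frequencies_rejected(self):
        with pytest.raises(ValueError, match="band"):
            bandpower_timecourse(np.zeros((1, 2, 500)), sfreq=500.0,
                                 band=(40.0, 60.0))


class TestSyntheticEndToEnd:
    def test_peak_latency_at_response(self, group_params):
        """The group-average response-locked lateralisation is most
        negative at the moment of the button press."""
        traces = simulate_traces(group_params, n=1500, seed=20)
        ep = generate_beta_epochs(traces, GeneratorSpec(seed=21))
        series = response_locked(compute_bpl(normalize_power(ep)), -0.3, 0.3)
        lat = peak_latency(series.values.mean(axis=0), series.times)
        assert abs(lat) < 0.02

    def test_regression_recovers_injected_previous_accuracy_effect(self):
        """Thresholds built with a pure previous-accuracy effect recover
        that coefficient with the right sign while other factors stay
        null."""
        rng = np.random.default_rng(22)
        parts, thr, pid = [], [], []
        for p in range(10):
            d = generate_task_design(320, seed=300 + p)
            d["correct"] = rng.random(len(d)) < 0.9
            d["prev_accuracy"] = np.where(
                np.r_[True, d["correct"].to_numpy()[:-1]], -1, 1)
            d["rt"] = rng.uniform(0.25, 0.55, len(d))
            d["miss"] = False
            d["first_of_block"] = d["trials_since_break"] == 0
            y = -0.4 * d["prev_accuracy"] + 0.5 * rng.standard_normal(len(d))
            parts.append(d)
            thr.append(y)
            pid.append(np.full(len(d), p))
        trials = pd.concat(parts, ignore_index=True)
        _, group = bpl_regression(np.concatenate(thr), trials,
                                  np.concatenate(pid), "eq7")
        tab = group.table
        assert tab.loc["prev_accuracy", "mean_value"] < 0
        assert tab.loc["prev_accuracy", "significant"]
        for other in ("incongruence", "distance", "rsi", "trial"):
            assert not tab.loc[other, "significant"]

    def test_posterror_boundary_raises_bpl_at_response(self):
        """Generating post-error trials with a higher decision boundary
        makes the previous-accuracy coefficient on the response-locked
        threshold negative (more negative lateralisation after errors)."""
        thr_all, trials_all, pid = [], [], []
        for p in range(8):
            spec = GeneratorSpec(seed=400 + p)
            rng = np.random.default_rng(500 + p)
            parts = []
            for prev, params in ((-1, spec.base),
                                 (1, spec.base.replace(a=spec.base.a * 1.3))):
                tr = simulate_traces(params, n=150, seed=int(rng.integers(2**31)))
                ep = generate_beta_epochs(tr, spec, seed=int(rng.integers(2**31)))
                series = response_locked(compute_bpl(normalize_power(ep)),
                                         -0.25, 0.25)
                t = bpl_threshold(series)
                meta = series.metadata.copy()
                meta["prev_accuracy"] = prev
                meta["bpl_thr"] = t
                parts.append(meta)
            both = pd.concat(parts, ignore_index=True)
            thr_all.append(both["bpl_thr"].to_numpy())
            trials_all.append(both)
            pid.append(np.full(len(both), p))
        trials = pd.concat(trials_all, ignore_index=True)
        # reduced factor set: only the factors the traces actually carry
        trials["rt"] = trials["rt"].clip(lower=0.05)
        coefs = []
        for p in np.unique(np.concatenate(pid)):
            sub = trials[np.concatenate(pid) == p]
            X = pd.DataFrame({
                "intercept": 1.0,
                "incongruence": np.where(sub["congruent"], -1.0, 1.0),
                "prev_accuracy": sub["prev_accuracy"].astype(float),
                "log_rt": np.log(sub["rt"].to_numpy(float))})
            from flankerddm import robust_regress
            coefs.append(robust_regress(X, np.concatenate(thr_all)[
                np.concatenate(pid) == p]).t_named())
        tmat = pd.DataFrame(coefs)
        from flankerddm import group_level_test
        gt = group_level_test(tmat.drop(columns="intercept"))
        assert gt.table.loc["prev_accuracy", "mean_value"] < 0
        assert gt.table.loc["prev_accuracy", "significant"]
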