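import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import sawtooth
from scipy.stats import norm, spearmanr

from pacwm.io_core import EPOCH_WINDOW, LFPEpochs
from pacwm.pac import (Comodulogram, _derangement, compute_comodulogram,
                       cycle_asymmetry, cycle_asymmetry_trace, detect_nesting,
                       load_contrast_by_area, modulation_index, pac_result,
                       select_pac_channels, single_trial_pac,
                       subsample_equal_loads, surrogate_z)
from pacwm.synthetic import SyntheticConfig, make_trials, simulate_lfp


def brute_force_mi(phase, amplitude, n_bins=18):
    """Independent oracle: explicit histogram loop, no shared code path."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    means = []
    for j in range(n_bins):
        if j < n_bins - 1:
            sel = (phase > edges[j]) & (phase <= edges[j + 1])
        else:
            sel = (phase > edges[j]) & (phase <= edges[j + 1] + 1e-12)
        if j == 0:
            sel |= phase <= edges[0]
        means.append(amplitude[sel].mean())
    p = np.array(means) / np.sum(means)
    h = -sum(pj * np.log(pj) for pj in p if pj > 0)
    return (np.log(n_bins) - h) / np.log(n_bins)


class TestModulationIndex:
    def test_constant_amplitude_gives_zero(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        mi, profile, _ = modulation_index(phase, np.ones_like(phase))
        assert mi == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(profile, 1 / 18, atol=1e-12)

    def test_single_bin_mass_gives_one(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 20000)
        # all amplitude mass in the single bin (0, 2*pi/18]
        amp = np.where((phase > 0) & (phase <= 2 * np.pi / 18), 1.0, 0.0)
        mi, _, pref = modulation_index(phase, amp)
        assert mi == pytest.approx(1.0, abs=1e-9)
        assert abs(pref - np.pi / 18) < 1e-9

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(2000, 6000)
            phase = rng.uniform(-np.pi, np.pi, n)
            amp = rng.gamma(2.0, 1.0, n) * (1 + 0.4 * np.cos(phase - 1.0))
            mi, _, _ = modulation_index(phase, amp)
            assert mi == pytest.approx(brute_force_mi(phase, amp), abs=1e-12)

    def test_cosine_modulated_preferred_phase(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 200000)
        amp = 1 + 0.5 * np.cos(phase)
        mi, _, pref = modulation_index(phase, amp)
        assert mi == pytest.approx(brute_force_mi(phase, amp), abs=1e-12)
        assert abs(pref) < 2 * np.pi / 18

    def test_invariant_to_positive_amplitude_rescaling(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 3000)
        amp = rng.gamma(2.0, 1.0, 3000) * (1 + 0.3 * np.cos(phase))
        mi1, _, _ = modulation_index(phase, amp)
        mi2, _, _ = modulation_index(phase, 73.2 * amp)
        assert mi1 == pytest.approx(mi2, abs=1e-14)

    def test_empty_bin_raises_naming_bin(self):
        phase = np.full(100, 0.1)
        with pytest.raises(ValueError, match="bin"):
            modulation_index(phase, np.ones(100))

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2 ** 20),
           scale=st.floats(1e-3, 1e3),
           depth=st.floats(0.0, 0.9))
    def test_mi_bounded_and_scale_invariant(self, seed, scale, depth):
        r = np.random.default_rng(seed)
        phase = r.uniform(-np.pi, np.pi, 2000)
        amp = r.gamma(2.0, 1.0, 2000) * (1 + depth * np.cos(phase))
        mi1, _, _ = modulation_index(phase, amp)
        mi2, _, _ = modulation_index(phase, scale * amp)
        assert 0.0 <= mi1 <= 1.0
        assert mi2 == pytest.approx(mi1, abs=1e-12)


class TestSurrogateZ:
    def test_derangement_has_no_fixed_points(self, rng):
        for n in (10, 23, 70):
            perm = _derangement(n, rng)
            assert not np.any(perm == np.arange(n))
            assert sorted(perm) == list(range(n))

    def test_null_z_standard_normal(self, rng):
        zs = []
        for _ in range(50):
            phase = rng.uniform(-np.pi, np.pi, (15, 400))
            amp = rng.gamma(2.0, 1.0, (15, 400))
            _, z, _, _, _ = surrogate_z(phase, amp, n_surr=60, rng=rng)
            zs.append(z)
        assert abs(np.mean(zs)) < 0.45  # MC bound at 50 draws

    def test_injected_coupling_detected(self, rng):
        cfg = SyntheticConfig(n_trials=40, load_split=(20, 20),
                              pac_depth={1: 0.8, 3: 0.8}, seed=5)
        trials = make_trials(cfg, rng)
        epochs, truth = simulate_lfp(cfg, trials, rng)
        res = pac_result(epochs, n_surr=80, rng=rng)
        assert res.z_mi > 5.0
        # preferred phase recovered near the injected coupling phase
        assert abs(np.angle(np.exp(1j * (res.preferred_phase
                                         - truth["phi_pref"])))) < 0.8

    def test_identical_trial_permutation_leaves_raw_mi_unchanged(self, rng):
        phase = rng.uniform(-np.pi, np.pi, (12, 300))
        amp = rng.gamma(2.0, 1.0, (12, 300)) * (1 + 0.4 * np.cos(phase))
        raw1, _, _, _, _ = surrogate_z(phase, amp, n_surr=20, rng=rng)
        perm = rng.permutation(12)
        raw2, _, _, _, _ = surrogate_z(phase[perm], amp[perm], n_surr=20, rng=rng)
        assert raw1 == pytest.approx(raw2, abs=1e-14)

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError, match="10 trials"):
            surrogate_z(rng.uniform(-1, 1, (5, 100)),
                        rng.gamma(2, 1, (5, 100)))


class TestChannelSelection:
    def test_threshold_is_normal_95th_percentile(self):
        from pacwm.stats import Z_CRIT_95
        assert Z_CRIT_95 == pytest.approx(norm.ppf(0.95))
        assert Z_CRIT_95 == pytest.approx(1.6449, abs=1e-4)

    def test_mean_z_selection_rule(self):
        phase_centres = np.arange(2.0, 15.0, 2.0)
        amp_centres = np.arange(30.0, 151.0, 5.0)
        z = np.zeros((7, 25))
        # put strong coupling only in theta x high-gamma cells
        pmask = np.isin(phase_centres, (4.0, 6.0))
        amask = (amp_centres >= 70) & (amp_centres <= 140)
        z[np.ix_(pmask, amask)] = 3.0
        como = Comodulogram(phase_centres, amp_centres, z, z * 0,
                            condition="all", n_trials_used=60)
        sel = select_pac_channels({"a": como}, gamma="high")
        assert sel["a"]
        sel_low = select_pac_channels({"a": como}, gamma="low")
        assert not sel_low["a"]

    def test_comodulogram_shape(self, rng):
        cfg = SyntheticConfig(n_trials=16, load_split=(8, 8), seed=2)
        trials = make_trials(cfg, rng)
        epochs, _ = simulate_lfp(cfg, trials, rng)
        como = compute_comodulogram(epochs, n_surr=12,
                                    phase_centres=np.array([4.0, 6.0]),
                                    amp_centres=np.array([80.0, 120.0]),
                                    rng=rng)
        assert como.z_mi.shape == (2, 2)
        assert np.all(np.isfinite(como.z_mi))
        full = Comodulogram(np.arange(2.0, 15.0, 2.0),
                            np.arange(30.0, 151.0, 5.0),
                            np.zeros((7, 25)), np.zeros((7, 25)), "all", 1)
        assert full.z_mi.shape == (7, 25)


class TestLoadContrast:
    def test_fdr_over_areas_and_direction(self, rng):
        # one area with a real load effect, two without
        areas = {}
        for name, delta in (("hippocampus", -1.0), ("amygdala", 0.0),
                            ("vmPFC", 0.0)):
            z1 = rng.normal(3.0, 1.0, 30)
            z3 = z1 + delta + rng.normal(0, 0.3, 30)
            areas[name] = (z1, z3)
        df = load_contrast_by_area(areas, n_perm=500, rng=rng)
        assert "p_fdr" in df.columns
        hip = df[df["area"] == "hippocampus"].iloc[0]
        assert hip["delta_z"] < 0
        assert hip["p_fdr"] < 0.05

    def test_subsample_equalizes_loads(self, default_session, rng):
        session, _ = default_session
        ch = session.lfp[0]
        keep = subsample_equal_loads(session.trials, ch.valid_trials, rng)
        loads = session.trials["load"].to_numpy()
        assert keep[loads == 1].sum() == keep[loads == 3].sum()
        correct = session.trials["correct"].to_numpy(bool)
        assert not np.any(keep & ~correct)


class TestSingleTrialPAC:
    def test_tracks_injected_trialwise_depth(self, rng):
        cfg = SyntheticConfig(n_trials=40, load_split=(20, 20),
                              pac_depth={1: 0.7, 3: 0.2},
                              pac_trial_jitter=0.5, seed=9)
        trials = make_trials(cfg, rng)
        epochs, truth = simulate_lfp(cfg, trials, rng)
        mi = single_trial_pac(epochs)
        rho, p = spearmanr(truth["kappa_trial"], mi)
        assert rho > 0.3 and p < 0.01

    def test_invalid_trial_yields_nan(self, rng):
        cfg = SyntheticConfig(n_trials=12, load_split=(6, 6), seed=3)
        trials = make_trials(cfg, rng)
        epochs, _ = simulate_lfp(cfg, trials, rng)
        epochs.valid_trials[4] = False
        mi = single_trial_pac(epochs)
        assert np.isnan(mi[4]) and np.isfinite(np.delete(mi, 4)).all()


class TestCycleAsymmetry:
    FS = 400.0

    def test_sinusoid_is_symmetric(self):
        t = np.arange(0, 3, 1 / self.FS)
        pt, rd, n = cycle_asymmetry_trace(np.sin(2 * np.pi * 5 * t), self.FS)
        assert pt == pytest.approx(0.5, abs=0.02)
        assert rd == pytest.approx(0.5, abs=0.02)
        assert n >= 10

    def test_sawtooth_rise_decay_sign(self):
        # width=0.9: slow rise, fast decay -> rise fraction ~0.9
        t = np.arange(0, 3, 1 / self.FS)
        x = sawtooth(2 * np.pi * 5 * t, width=0.9)
        _, rd, _ = cycle_asymmetry_trace(x, self.FS)
        assert rd == pytest.approx(0.9, abs=0.05)

    def test_time_reversal_flips_rise_decay(self):
        t = np.arange(0, 3, 1 / self.FS)
        x = sawtooth(2 * np.pi * 5 * t, width=0.8)
        _, rd_fwd, _ = cycle_asymmetry_trace(x, self.FS)
        _, rd_rev, _ = cycle_asymmetry_trace(x[::-1], self.FS)
        assert rd_fwd + rd_rev == pytest.approx(1.0, abs=0.05)

    def test_too_few_cycles_missing(self):
        t = np.arange(0, 0.3, 1 / self.FS)
        pt, rd, n = cycle_asymmetry_trace(np.sin(2 * np.pi * 5 * t), self.FS)
        assert n < 3 and np.isnan(pt)

    def test_per_trial_frame(self, rng):
        cfg = SyntheticConfig(n_trials=12, load_split=(6, 6), seed=7)
        trials = make_trials(cfg, rng)
        epochs, _ = simulate_lfp(cfg, trials, rng)
        df = cycle_asymmetry(epochs)
        assert len(df) == 12
        assert df["n_cycles"].min() >= 3
        assert df["pt"].between(0, 1).all()


class TestNesting:
    def _epochs_with_bursts(self, rng, burst: bool):
        fs = 400.0
        n = int(3.5 * fs)
        t = EPOCH_WINDOW[0] + np.arange(n) / fs
        samples = np.empty((20, n))
        for i in range(20):
            theta = 2 * np.pi * 5 * t + rng.uniform(-np.pi, np.pi)
            x = 10 * np.cos(theta) + rng.standard_normal(n)
            if burst:
                # gamma bursts riding on the theta peak
                env = 8 * np.exp(1.5 * (np.cos(theta) - 1))
                x = x + env * np.cos(2 * np.pi * 90 * t
                                     + rng.uniform(0, 2 * np.pi))
            samples[i] = x
        return LFPEpochs(channel_id="c", region="hippocampus", fs=fs,
                         samples=samples, window=EPOCH_WINDOW,
                         valid_trials=np.ones(20, bool))

    def test_bursts_at_theta_peak_are_nested(self, rng):
        res = detect_nesting(self._epochs_with_bursts(rng, burst=True))
        assert res.nested
        assert res.reliable

    def test_pure_theta_not_nested(self, rng):
        res = detect_nesting(self._epochs_with_bursts(rng, burst=False))
        assert not res.nested
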