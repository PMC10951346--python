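"""Modulation index, phase/amplitude extraction and MI aggregation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tgckit.eeg import EpochedEEG, FRONTAL_ELECTRODES
from tgckit.synthetic import SignalSpec, generate_coupled_eeg
from tgckit.tgc import (
    TGCBandConfig,
    compute_participant_tgc,
    extract_phase_amplitude,
    frontal_average,
    modulation_index,
    weighted_mi,
)


def _uniform_phases(n=36_000):
    return np.linspace(-np.pi + 1e-9, np.pi, n)


class TestModulationIndex:
    def test_constant_amplitude_gives_zero(self):
        assert modulation_index(_uniform_phases(), np.ones(36_000)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_bin_concentration_approaches_one(self):
        phase = np.full(1000, 0.05)  # all mass in one of 18 bins
        amp = np.ones(1000)
        with pytest.warns(RuntimeWarning, match="empty"):
            mi = modulation_index(phase, amp, 18)
        assert mi > 0.99

    def test_gain_invariance(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.gamma(2.0, 1.0, 5000)
        mi = modulation_index(phase, amp)
        assert modulation_index(phase, 37.5 * amp) == pytest.approx(mi, abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.integers(4, 36))
    def test_mi_in_unit_interval(self, seed, n_bins):
        r = np.random.default_rng(seed)
        phase = r.uniform(-np.pi, np.pi, 500)
        amp = r.gamma(1.5, 1.0, 500) + 1e-6
        assert 0.0 <= modulation_index(phase, amp, n_bins) <= 1.0

    def test_all_zero_amplitude_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            modulation_index(_uniform_phases(100), np.zeros(100))

    def test_monotone_in_modulation_depth(self):
        cfg = TGCBandConfig()
        mis = []
        for chi in (0.1, 0.8):
            spec = SignalSpec(chi=chi, seed=42, n_epochs=10, n_channels=1,
                              epoch_length=2.0, sample_rate=500.0)
            eeg = generate_coupled_eeg(spec)
            ph, am = zip(*(
                extract_phase_amplitude(eeg.data[e, 0], eeg.sample_rate, cfg)
                for e in range(eeg.n_epochs)
            ))
            mis.append(modulation_index(np.concatenate(ph), np.concatenate(am)))
        assert mis[1] > mis[0]


class TestExtractPhaseAmplitude:
    def test_theta_sinusoid_phase_velocity(self):
        fs, f = 500.0, 6.0
        t = np.arange(int(5 * fs)) / fs
        phase, _ = extract_phase_amplitude(np.sin(2 * np.pi * f * t), fs)
        rate = np.diff(np.unwrap(phase)) * fs / (2 * np.pi)
        assert np.median(rate) == pytest.approx(f, rel=0.01)

    def test_gamma_sinusoid_envelope(self):
        fs, f, A = 500.0, 40.0, 2.7
        t = np.arange(int(5 * fs)) / fs
        _, amp = extract_phase_amplitude(A * np.sin(2 * np.pi * f * t), fs)
        assert np.median(amp) == pytest.approx(A, rel=0.05)

    def test_white_noise_null_mi_small(self, rng):
        x = rng.standard_normal(int(30 * 500))
        phase, amp = extract_phase_amplitude(x, 500.0)
        assert modulation_index(phase, amp, 18) < 0.05

    def test_too_short_epoch_names_minimum(self):
        cfg = TGCBandConfig()
        with pytest.raises(ValueError, match=str(cfg.min_samples(500.0))):
            extract_phase_amplitude(np.zeros(50), 500.0, cfg)

    def test_mi_invariant_to_epoch_gain(self):
        spec = SignalSpec(chi=0.6, seed=1, n_epochs=4, n_channels=1,
                          epoch_length=2.0, sample_rate=500.0)
        eeg = generate_coupled_eeg(spec)
        mis = []
        for gain in (1.0, 250.0):
            ph, am = extract_phase_amplitude(gain * eeg.data[0, 0], eeg.sample_rate)
            mis.append(modulation_index(ph, am))
        assert mis[0] == pytest.approx(mis[1], abs=1e-12)


class TestFrontalAverage:
    def test_mean_of_constants(self):
        assert frontal_average({c: 0.42 for c in FRONTAL_ELECTRODES}) == pytest.approx(0.42)

    def test_missing_electrode_named(self):
        vals = {c: 0.1 for c in FRONTAL_ELECTRODES if c != "Fz"}
        with pytest.raises(ValueError, match="Fz"):
            frontal_average(vals)

    def test_matches_numpy_mean(self, rng):
        vals = dict(zip(FRONTAL_ELECTRODES, rng.random(9)))
        assert frontal_average(vals) == pytest.approx(np.mean(list(vals.values())))


class TestWeightedMI:
    def test_equal_proportions_literal(self):
        m = 0.12
        assert weighted_mi([m] * 4, [0.25] * 4, "literal") == pytest.approx(m / 4)

    def test_degenerate_proportions_both_modes(self):
        mi = [0.004, 0.9, 0.9, 0.9]
        p = [1.0, 0.0, 0.0, 0.0]
        assert weighted_mi(mi, p, "literal") == pytest.approx(0.001)
        assert weighted_mi(mi, p, "normalized") == pytest.approx(0.004)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_dot_product_oracle(self, seed):
        r = np.random.default_rng(seed)
        p = r.dirichlet(np.ones(4))
        mi = r.random(4)
        expected = float(np.dot(p, mi))
        assert weighted_mi(mi, p, "normalized") == pytest.approx(expected)
        assert weighted_mi(mi, p, "literal") == pytest.approx(expected / 4)

    @given(st.integers(0, 2**31 - 1))
    def test_normalized_mode_is_convex_combination(self, seed):
        r = np.random.default_rng(seed)
        p = r.dirichlet(np.ones(4))
        mi = r.random(4)
        w = weighted_mi(mi, p, "normalized")
        assert mi.min() - 1e-12 <= w <= mi.max() + 1e-12

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            weighted_mi([0.1] * 4, [0.3, 0.3, 0.3, 0.3])


@pytest.fixture(scope="module")
def eeg():
    return generate_coupled_eeg(
        SignalSpec(chi=0.7, seed=2, n_epochs=8, epoch_length=1.5, sample_rate=500.0)
    )


class TestComputeParticipantTGC:
    def test_result_structure(self, eeg):
        res = compute_participant_tgc(eeg)
        assert res.weighting == "literal"
        props = np.array(list(res.epoch_proportions.values()))
        assert props.sum() == pytest.approx(1.0)
        assert all(0.0 <= v <= 1.0 for v in res.mi_by_trial_type.values())

    def test_literal_is_quarter_of_normalized(self, eeg):
        lit = compute_participant_tgc(eeg, weighting="literal").weighted_mi
        nrm = compute_participant_tgc(eeg, weighting="normalized").weighted_mi
        assert lit == pytest.approx(nrm / 4)

    def test_missing_frontal_channel_rejected(self, eeg):
        crippled = EpochedEEG(
            data=eeg.data[:, :8],
            sample_rate=eeg.sample_rate,
            channel_labels=eeg.channel_labels[:8],
            trial_result=eeg.trial_result,
        )
        with pytest.raises(ValueError, match="Fz"):
            compute_participant_tgc(crippled)
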