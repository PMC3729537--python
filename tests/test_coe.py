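"""Coefficient of Expressiveness: PCA relevance index and directional profiles."""

import numpy as np
import pytest

from emgintent import coe, synth
from emgintent.coe import CoeTrial, abnormality_flags, coe_profile, coe_trial
from emgintent.errors import ChannelMismatchError, ConfigError
from emgintent.preprocess import Window


def _window(signals, names=None, direction=0.0, subject="S"):
    signals = np.atleast_2d(signals)
    names = names or tuple(f"M{i}" for i in range(signals.shape[0]))
    return Window(signals=signals, sampling_rate=1000.0, channel_names=tuple(names),
                  direction_deg=direction, onset_sample=0, subject_id=subject)


def _coe_trial_stub(values, direction, names=None):
    values = np.asarray(values, dtype=float)
    names = names or tuple(f"M{i}" for i in range(values.size))
    return CoeTrial(
        channel_names=tuple(names), direction_deg=direction,
        k_values=values, raw_coe=values, coe_values=values,
        relevant=values > 0.7, n_components=1,
        eigenvalues=np.ones(values.size), correlations=np.eye(values.size),
    )


class TestCoeTrial:
    def test_rank_one_input_concentrates_on_one_muscle(self, rng):
        strong = rng.standard_normal(2000)
        signals = np.stack([strong, 1e-6 * rng.standard_normal(2000),
                            1e-6 * rng.standard_normal(2000)])
        result = coe_trial(_window(signals))
        assert result.coe_values[0] == 1.0
        assert np.all(result.coe_values[1:] == 0.0)

    def test_identical_channels_all_maximal(self, rng):
        x = rng.standard_normal(2000)
        result = coe_trial(_window(np.stack([x, x, x])))
        assert np.allclose(result.coe_values, 1.0)

    def test_two_independent_equal_variance_muscles(self, rng):
        signals = rng.standard_normal((2, 10000))
        result = coe_trial(_window(signals))
        assert result.n_components == 2  # 80% threshold forces both PCs
        assert np.all(np.abs(result.coe_values - 1.0) < 0.05)

    def test_subthreshold_values_stored_as_zero(self, rng):
        signals = rng.standard_normal((4, 5000)) * np.array([[1.0], [0.8], [0.5], [0.2]])
        result = coe_trial(_window(signals))
        assert np.array_equal(
            result.coe_values, np.where(result.raw_coe > 0.7, result.raw_coe, 0.0)
        )

    def test_exactly_one_muscle_attains_unity(self, healthy_windows):
        for w in healthy_windows[:10]:
            result = coe_trial(w)
            assert result.coe_values.max() == 1.0
            assert np.all((result.coe_values >= 0) & (result.coe_values <= 1))

    def test_common_scale_invariance(self, rng):
        signals = rng.standard_normal((3, 1000))
        a = coe_trial(_window(signals))
        b = coe_trial(_window(signals * 37.5))
        assert np.allclose(a.coe_values, b.coe_values, atol=1e-10)

    def test_component_count_is_minimal_prefix(self, healthy_windows):
        """n is the smallest prefix of eigenvalues reaching 80% variance
        (checked against brute force over all prefixes)."""
        for w in healthy_windows[:10]:
            result = coe_trial(w)
            fractions = np.cumsum(result.eigenvalues) / result.eigenvalues.sum()
            brute = min(i + 1 for i in range(fractions.size) if fractions[i] >= 0.80 - 1e-12)
            assert result.n_components == brute

    def test_component_count_monotone_in_variance_threshold(self, healthy_windows):
        w = healthy_windows[0]
        counts = [coe_trial(w, variance_threshold=v).n_components
                  for v in (0.80, 0.90, 0.99, 1.0)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_constant_channel_has_zero_relevance(self, rng):
        signals = np.stack([rng.standard_normal(500), np.zeros(500)])
        result = coe_trial(_window(signals))
        assert result.coe_values[1] == 0.0

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ConfigError):
            coe_trial(_window(rng.standard_normal((5, 4))))


class TestCoeProfile:
    def test_identical_trials_have_zero_half_width(self):
        trials = [_coe_trial_stub([1.0, 0.0], 90.0) for _ in range(4)]
        profile = coe_profile(trials)
        assert np.allclose(profile.half_width, 0.0)

    def test_alternating_values_hand_computed_half_width(self):
        # CoE values {1, 0, 1, 0}: mean 0.5, sd 0.5774, 1.96*sd/2 = 0.566
        trials = [_coe_trial_stub([v], 0.0) for v in (1.0, 0.0, 1.0, 0.0)]
        profile = coe_profile(trials)
        assert profile.coe_m[0, 0] == pytest.approx(0.5)
        assert profile.half_width[0, 0] == pytest.approx(0.566, abs=0.001)

    def test_single_trial_direction_flags_half_width(self):
        profile = coe_profile([_coe_trial_stub([1.0], 0.0)])
        assert np.isnan(profile.half_width[0, 0])

    def test_healthy_agonists_attain_maximal_coe(self, healthy_subject, healthy_windows):
        """Directional tuning recovery: each muscle's CoE_M peaks at the
        cardinal direction nearest its generator preferred direction."""
        profile = coe_profile([coe_trial(w) for w in healthy_windows])
        for i, muscle in enumerate(profile.muscles):
            pref = healthy_subject.muscle(muscle).preferred_direction
            best = profile.directions[int(np.argmax(profile.coe_m[i]))]
            delta = abs((best - pref + 180.0) % 360.0 - 180.0)
            assert delta <= 45.0, f"{muscle}: argmax {best} vs preferred {pref}"


class TestAbnormalityFlags:
    def directions(self):
        return (0.0, 90.0, 180.0, 270.0)

    def _profile(self, by_muscle):
        muscles = tuple(by_muscle)
        coe_m = np.array([by_muscle[m] for m in muscles], dtype=float)
        return coe.CoeProfile(
            muscles=muscles, directions=self.directions(), coe_m=coe_m,
            half_width=np.zeros_like(coe_m), n_trials=np.full(4, 5),
        )

    def test_identical_profiles_raise_no_flags(self):
        ref = self._profile({"TR": [0, 1, 0, 0], "BI": [0, 0, 0, 1]})
        findings = abnormality_flags(ref, ref)
        assert not any(f.any for f in findings.values())

    def test_shifted_preferred_direction_flagged(self):
        ref = self._profile({"TR": [0, 1, 0, 0]})
        pat = self._profile({"TR": [0, 0, 0, 1]})
        assert abnormality_flags(pat, ref)["TR"].preferred_shift

    def test_flat_patient_profile_flags_loss_of_tuning(self):
        ref = self._profile({"TR": [0, 1, 0, 0]})
        pat = self._profile({"TR": [0.4, 0.45, 0.4, 0.42]})
        assert abnormality_flags(pat, ref)["TR"].loss_of_tuning

    def test_opposite_direction_relevance_flags_coactivation(self):
        ref = self._profile({"TR": [0, 1, 0, 0]})
        pat = self._profile({"TR": [0, 0.9, 0, 0.8]})  # North and South both active
        assert abnormality_flags(pat, ref)["TR"].antagonist_coactivation

    def test_back_muscle_recruitment_flags_trunk_involvement(self):
        ref = self._profile({"LT": [0.1, 0.05, 0.1, 0.0]})
        pat = self._profile({"LT": [0.9, 0.1, 0.1, 0.0]})
        assert abnormality_flags(pat, ref)["LT"].trunk_involvement

    def test_mismatched_muscle_sets_rejected(self):
        a = self._profile({"TR": [0, 1, 0, 0]})
        b = self._profile({"BI": [0, 1, 0, 0]})
        with pytest.raises(ChannelMismatchError):
            abnormality_flags(a, b)

    def test_severity_one_coupling_detected_from_generated_data(self):
        """A severity-1 subject with BI-TR synergy coupling shows antagonist
        co-activation in the decoded relevance profiles."""
        from emgintent import preprocess

        design = synth.SessionDesign(
            directions=(90.0, 0.0, 270.0, 180.0), durations=(600.0,), repetitions=8
        )
        subject = synth.make_stroke_subject(3, 1.0)
        # isolate the synergy: keep coupling, suppress direction shifts
        import dataclasses
        subject = dataclasses.replace(
            subject,
            impairment=dataclasses.replace(
                subject.impairment, direction_shift={}, trial_gain_cv=0.0
            ),
        )
        windows = preprocess.window_session(synth.simulate_session(subject, design))
        profile = coe_profile([coe_trial(w) for w in windows])
        flagged = {
            m for m, f in abnormality_flags(profile, profile).items()
            if f.antagonist_coactivation
        }
        assert flagged & {"BI", "TR", "DP", "DA"}
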