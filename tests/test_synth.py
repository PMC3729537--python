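"""Generator tests: directional tuning, determinism, protocols, stroke model."""

from collections import Counter

import numpy as np
import pytest

from emgintent import synth
from emgintent.errors import ConfigError


class TestSubjectModels:
    def test_healthy_subject_matches_directional_map(self, healthy_subject):
        """Triceps drives North; deltoids East; trapezius/biceps South;
        pectoralis/anterior deltoid West."""
        pref = {m.name: m.preferred_direction for m in healthy_subject.muscles}
        assert pref["TR"] == 90.0
        def near(angle, target, tol=45.0):
            return abs((angle - target + 180.0) % 360.0 - 180.0) <= tol
        assert near(pref["PM"], 180.0) and near(pref["DA"], 180.0)
        assert near(pref["DM"], 0.0) and near(pref["DP"], 0.0)
        assert near(pref["UT"], 270.0) and near(pref["BI"], 270.0)

    def test_healthy_subject_deterministic(self):
        assert synth.make_healthy_subject(1) == synth.make_healthy_subject(1)

    def test_seed_changes_gains_not_directions(self):
        a, b = synth.make_healthy_subject(1), synth.make_healthy_subject(2)
        for ma, mb in zip(a.muscles, b.muscles):
            assert ma.preferred_direction == mb.preferred_direction
            assert ma.tuning_gain != mb.tuning_gain

    def test_stroke_severity_zero_is_healthy(self):
        assert synth.make_stroke_subject(3, 0.0) == synth.make_healthy_subject(3)

    def test_stroke_severity_one_has_coupling(self):
        subject = synth.make_stroke_subject(3, 1.0)
        pairs = {frozenset((a, b)): g for a, b, g in subject.impairment.coactivation_coupling}
        assert pairs[frozenset(("BI", "TR"))] > 0
        assert pairs[frozenset(("DP", "DA"))] > 0

    def test_stroke_severity_interpolates_monotonically(self):
        lo = synth.make_stroke_subject(3, 0.0).impairment.trial_gain_cv
        mid = synth.make_stroke_subject(3, 0.5).impairment.trial_gain_cv
        hi = synth.make_stroke_subject(3, 1.0).impairment.trial_gain_cv
        assert lo < mid < hi
        shift_mid = synth.make_stroke_subject(3, 0.5).impairment.direction_shift
        shift_hi = synth.make_stroke_subject(3, 1.0).impairment.direction_shift
        for name in shift_mid:
            assert abs(shift_mid[name]) < abs(shift_hi[name])

    @pytest.mark.parametrize("severity", [-0.1, 1.5])
    def test_stroke_severity_out_of_range(self, severity):
        with pytest.raises(ConfigError):
            synth.make_stroke_subject(1, severity)


class TestSessionDesigns:
    @pytest.mark.parametrize(
        "directions,durations,reps,expected",
        [
            (4, 3, 5, 60),   # healthy protocol: 4 targets x 3 durations x 5
            (8, 1, 5, 40),
            (8, 1, 10, 80),  # patient protocol: two electrode blocks of 5
        ],
    )
    def test_trial_counts(self, directions, durations, reps, expected):
        design = synth.SessionDesign(
            directions=tuple(np.linspace(0, 360, directions, endpoint=False)),
            durations=tuple([1000.0, 600.0, 300.0][:durations]),
            repetitions=reps,
        )
        assert design.n_trials == expected

    def test_protocol_constructors(self):
        assert synth.healthy_protocol().n_trials == 60
        assert synth.patient_protocol().n_trials == 80

    def test_zero_repetitions_rejected(self):
        with pytest.raises(ConfigError):
            synth.SessionDesign(directions=(0.0, 90.0), durations=(600.0,), repetitions=0)

    def test_duplicate_directions_rejected(self):
        with pytest.raises(ConfigError):
            synth.SessionDesign(directions=(0.0, 360.0), durations=(600.0,), repetitions=1)


class TestSimulation:
    def test_session_is_bit_identical(self, healthy_subject):
        design = synth.SessionDesign(directions=(0.0, 90.0), durations=(300.0,), repetitions=2)
        a = synth.simulate_session(healthy_subject, design)
        b = synth.simulate_session(healthy_subject, design)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.signals, tb.signals)
            assert ta.direction_deg == tb.direction_deg

    def test_position_endpoint_reaches_target(self, healthy_subject, rng):
        trial = synth.simulate_trial(healthy_subject, 45.0, 600.0, rng, target_distance=0.14)
        start = trial.position[:, 0]
        end = trial.position[:, -1]
        assert np.linalg.norm(end - start) == pytest.approx(0.14, abs=1e-9)

    def test_onset_sample_marks_motion_start(self, healthy_subject, rng):
        trial = synth.simulate_trial(healthy_subject, 0.0, 600.0, rng)
        onset = trial.onset_sample
        assert np.allclose(trial.position[:, :onset], trial.position[:, :1])
        assert np.linalg.norm(trial.position[:, onset + 50] - trial.position[:, 0]) > 0

    def test_zero_gain_channels_are_pure_baseline(self, rng):
        """With all tuning gains at zero the windowed mean absolute value is
        the folded-normal mean sd * sqrt(2/pi)."""
        muscles = tuple(
            synth.MuscleModel(name=n, preferred_direction=d, tuning_gain=0.0,
                              antagonist_floor=0.0, baseline_noise_sd=8e-3)
            for n, d in [("A", 0.0), ("B", 90.0)]
        )
        subject = synth.SubjectModel(muscles=muscles, seed=0)
        means = []
        for _ in range(30):
            trial = synth.simulate_trial(subject, 0.0, 600.0, rng)
            sl = slice(trial.onset_sample - 100, trial.onset_sample + 100)
            means.append(np.mean(np.abs(trial.signals[:, sl])))
        expected = 8e-3 * np.sqrt(2.0 / np.pi)
        assert np.mean(means) == pytest.approx(expected, rel=0.10)

    def test_tuning_recovery(self, healthy_subject):
        """Per direction, the channel with maximal windowed activity is one
        of the generator's ground-truth agonists (20 trials/direction)."""
        rng = np.random.default_rng(7)
        for direction in (90.0, 0.0, 270.0, 180.0):
            winners = Counter()
            for _ in range(20):
                trial = synth.simulate_trial(healthy_subject, direction, 600.0, rng)
                sl = slice(trial.onset_sample - 100, trial.onset_sample + 100)
                activity = np.mean(np.abs(trial.signals[:, sl]), axis=1)
                winners[trial.channel_names[int(np.argmax(activity))]] += 1
            modal = winners.most_common(1)[0][0]
            assert modal in synth.agonists_for(healthy_subject, direction)

    def test_antagonist_activity_increases_with_severity(self):
        """Mean antagonist windowed activity is non-decreasing in severity
        (co-contraction floor rises)."""
        levels = []
        for severity in (0.0, 0.5, 1.0):
            subject = synth.make_stroke_subject(5, severity)
            # keep the healthy map so "antagonist of North" is well defined
            rng = np.random.default_rng(42)
            vals = []
            for _ in range(10):
                trial = synth.simulate_trial(subject, 90.0, 600.0, rng)
                sl = slice(trial.onset_sample - 100, trial.onset_sample + 100)
                i = trial.channel_names.index("UT")  # South-preferring antagonist
                vals.append(np.mean(np.abs(trial.signals[i, sl])))
            levels.append(np.mean(vals))
        assert levels[0] <= levels[1] <= levels[2]


class TestSessionIO:
    def test_roundtrip(self, healthy_subject, tmp_path):
        design = synth.SessionDesign(directions=(0.0, 90.0), durations=(300.0,), repetitions=1)
        trials = synth.simulate_session(healthy_subject, design)
        manifest = synth.write_session(trials, tmp_path)
        loaded = synth.read_session(manifest)
        assert len(loaded) == len(trials)
        for orig, back in zip(trials, loaded):
            assert back.channel_names == orig.channel_names
            assert back.direction_deg == orig.direction_deg
            assert back.onset_sample == orig.onset_sample
            assert np.allclose(back.signals, orig.signals, atol=1e-12)
            assert np.allclose(back.position, orig.position, atol=1e-12)

    def test_yaml_config(self, tmp_path):
        cfg = tmp_path / "gen.yaml"
        cfg.write_text(
            "subject:\n  kind: stroke\n  seed: 4\n  severity: 0.5\n"
            "design:\n  protocol: patient\n"
        )
        subject, design = synth.load_generator_config(cfg)
        assert subject == synth.make_stroke_subject(4, 0.5)
        assert design.n_trials == 80
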