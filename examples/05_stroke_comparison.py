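"""Healthy vs stroke-like decoding: individual calibration and cross-group.

Sweeps impairment severity over {0, 0.5, 1} and decodes each cohort with
individually calibrated 70/30 holdouts, then trains on healthy subjects and
tests on the severity-1 cohort.  Accuracy should fall with severity, and
the healthy-trained classifier should do worse on impaired subjects than
their own individually calibrated one — decoding intent from abnormal
muscle patterns needs per-patient calibration, and even that degrades.
"""

from emgintent import classify, preprocess, synth

design = synth.healthy_protocol()


def cohort(severity, seeds):
    out = {}
    for s in seeds:
        subject = synth.make_stroke_subject(s, severity)
        out[subject.subject_id] = preprocess.window_session(
            synth.simulate_session(subject, design)
        )
    return out


cohorts = {}
for severity in (0.0, 0.5, 1.0):
    cohorts[severity] = cohort(severity, range(200, 203))
    result = classify.run_validation(
        cohorts[severity],
        classify.SplitSpec(design="individual_holdout", n_iterations=5, seed=3),
    )
    print(f"severity {severity:.1f}: individually calibrated accuracy "
          f"{result.mean_accuracy:5.1f} %")

healthy = {}
for s in range(1, 6):
    subject = synth.make_healthy_subject(s)
    healthy[subject.subject_id] = preprocess.window_session(
        synth.simulate_session(subject, design)
    )
cross = classify.run_validation(
    healthy,
    classify.SplitSpec(design="cross_group", n_iterations=1, seed=3),
    test_sessions=cohorts[1.0],
)
print(f"train healthy / test severity-1: {cross.mean_accuracy:5.1f} % "
      "(near the 25% chance rate: the healthy map does not transfer)")
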