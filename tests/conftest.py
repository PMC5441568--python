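import numpy as np
import pytest

from icnpipe import classify, synthgen


@pytest.fixture(scope="session")
def atlas8():
    return synthgen.make_atlas((16, 16, 8), 8, seed=1)


@pytest.fixture(scope="session")
def tiny_cohort(atlas8):
    """4 + 4 subjects, 3 follow-ups, 40 volumes: structural checks only."""
    cfg = synthgen.CohortConfig(
        n_patients=4,
        n_controls=4,
        n_followup_ect=2,
        n_followup_med=1,
        n_volumes=40,
        k_components=8,
        affected=(0, 1, 2, 3),
        delta=1.5,
        seed=5,
    )
    return synthgen.simulate_cohort(atlas8, cfg)


@pytest.fixture(scope="session")
def small_grid():
    return [classify.SVMParams("linear", 0.1), classify.SVMParams("linear", 1.0)]


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def truth_features(cohort, session="baseline"):
    """FeatureSet built from the generator's true subject maps (z-scored),
    bypassing ICA estimation: the planted-truth route for classifier tests."""
    if session == "baseline":
        sids = [s.subject_id for s in cohort.baseline_scans()]
    else:
        sids = [s.subject_id for s in cohort.followup_scans()]
    data = []
    for sid in sids:
        m = cohort.truth.subject_maps[(sid, session)]
        data.append((m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True))
    fs = classify.FeatureSet(
        data=np.stack(data),
        component_labels=[f"IC{c}" for c in range(cohort.atlas.k)],
        subject_ids=sids,
        sessions=[session] * len(sids),
    )
    labels = ["patient" if s.startswith("P") else "control" for s in sids]
    return fs, labels
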