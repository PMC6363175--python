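import numpy as np
import pandas as pd
import pytest

import cvaffect as cv
from cvaffect.model import (ModelSpec, average_coder_ratings, predict_ratings,
                            split_by_participant, train_rating_model)


@pytest.fixture(scope="session")
def medium_study():
    """A 30-participant synthetic study (1,260 recordings before filtering)."""
    cfg = cv.SimulationConfig(n_participants=30, seed=42)
    recordings, truth, ratings = cv.simulate_study(cfg)
    features, report = cv.featurize_recordings(recordings)
    return {"config": cfg, "recordings": recordings, "truth": truth,
            "ratings": ratings, "features": features, "report": report}


@pytest.fixture(scope="session")
def pos_model(medium_study):
    """Default-spec forest fit to all retained recordings, positive valence."""
    features = medium_study["features"]
    outcome = average_coder_ratings(medium_study["ratings"], "positive").loc[features.index]
    model = train_rating_model(features, outcome, ModelSpec(), seed=123)
    return model, outcome


@pytest.fixture(scope="session")
def pos_eval(medium_study):
    """Held-out predictions for the positive-valence model on a 66/34 split."""
    features = medium_study["features"]
    outcome = average_coder_ratings(medium_study["ratings"], "positive").loc[features.index]
    plan = split_by_participant(features, seed=7)
    model = train_rating_model(features.loc[plan.train_ids],
                               outcome.loc[plan.train_ids], ModelSpec(), seed=8)
    pred = predict_ratings(model, features.loc[plan.test_ids])
    return {"pred": pred, "outcome": outcome.loc[plan.test_ids],
            "pids": features.loc[plan.test_ids, "participant_id"], "plan": plan}


@pytest.fixture()
def tiny_config():
    return cv.SimulationConfig(n_participants=4, trials_per_condition=2,
                               duration=2.0, seed=5)


def make_recording(flags, evidence=None, frame_rate=30.0, rec_id="R1", pid="P1",
                   au_labels=(1, 2)):
    """Hand-built AUTimeSeries for filter/featurization tests."""
    flags = np.asarray(flags, bool)
    n = len(flags)
    if evidence is None:
        evidence = np.ones((n, len(au_labels)))
    return cv.AUTimeSeries(
        recording_id=rec_id, participant_id=pid, condition="normal",
        block_valence="positive", timestamps=np.arange(n) / frame_rate,
        face_detected=flags, evidence=np.asarray(evidence, float),
        au_labels=tuple(au_labels))
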