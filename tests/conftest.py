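import numpy as np
import pandas as pd
import pytest

from voxpitch.emotion_task import EMOTIONS, SPEAKERS, TRIALS_PER_EMOTION_SPEAKER


def perfect_session() -> pd.DataFrame:
    """Balanced 120-trial session in which every response is correct."""
    rows = []
    i = 0
    for emotion in EMOTIONS:
        for speaker in SPEAKERS:
            for _ in range(TRIALS_PER_EMOTION_SPEAKER):
                i += 1
                rows.append({"trial_id": i, "speaker": speaker,
                             "true_emotion": emotion,
                             "response_emotion": emotion})
    return pd.DataFrame(rows)


@pytest.fixture
def balanced_session() -> pd.DataFrame:
    return perfect_session()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
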