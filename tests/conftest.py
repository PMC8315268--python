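import warnings

import numpy as np
import pytest

from prespeech.core import FaceTrack
from prespeech.labial import PronLexicon


@pytest.fixture(scope="session")
def lexicon() -> PronLexicon:
    return PronLexicon.builtin()


@pytest.fixture(autouse=True)
def _quiet_df_warnings():
    """Satterthwaite boundary warnings are expected in degenerate fixtures."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="degenerate variance of the variance estimate"
        )
        warnings.filterwarnings("ignore", message="slice .*no random structure")
        yield


def make_track(
    areas=None, quads=None, fps=30.0, speaker_id="S", success=None
) -> FaceTrack:
    """Build a minimal FaceTrack from per-frame lip quads (or flat areas
    via a diamond whose primary-formula area equals the requested value)."""
    if quads is None:
        areas = np.asarray(areas, float)
        w = 10.0
        h = areas / (6.0 * w)
        n = areas.size
        quads = np.empty((n, 4, 2))
        quads[:, 0] = np.column_stack([-w * np.ones(n), np.zeros(n)])
        quads[:, 1] = np.column_stack([np.zeros(n), -h])
        quads[:, 2] = np.column_stack([w * np.ones(n), np.zeros(n)])
        quads[:, 3] = np.column_stack([np.zeros(n), h])
    quads = np.asarray(quads, float)
    n = quads.shape[0]
    points = {i: np.zeros((n, 2)) for i in range(48, 68)}
    for j, lm in enumerate((48, 51, 54, 57)):
        points[lm] = quads[:, j]
    return FaceTrack(
        speaker_id=speaker_id,
        fps=fps,
        frame=np.arange(n),
        timestamp_ms=np.arange(n) * (1000.0 / fps),
        success=np.ones(n, bool) if success is None else np.asarray(success, bool),
        points=points,
    )
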