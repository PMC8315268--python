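"""Core domain types shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from prespeech.errors import ValidationError

#: Outer-lip landmarks used for the area computation: left corner, top
#: center, right corner, bottom center of the outer lip contour.
LIP_QUAD_LANDMARKS = (48, 51, 54, 57)

#: All outer + inner lip landmarks of the 68-point facial landmark scheme.
LIP_LANDMARKS = tuple(range(48, 68))


@dataclass(frozen=True)
class UtteranceRecord:
    """One annotated acoustic utterance.

    ``onset_ms``/``offset_ms`` bound the *acoustic* utterance (onset = first
    notable swell in audio intensity); the transcript is a whitespace-
    separated token sequence preserved verbatim from the annotation tier.
    """

    speaker_id: str
    onset_ms: int
    offset_ms: int
    transcript: str

    def __post_init__(self):
        if self.offset_ms <= self.onset_ms:
            raise ValidationError(
                f"utterance offset ({self.offset_ms}) must exceed onset "
                f"({self.onset_ms}) for speaker {self.speaker_id!r}"
            )
        if self.onset_ms < 0:
            raise ValidationError(f"negative onset {self.onset_ms}")
        if not self.transcript.strip():
            raise ValidationError("transcript has no tokens")

    @property
    def tokens(self) -> list[str]:
        return self.transcript.split()

    @property
    def word_count(self) -> int:
        return len(self.tokens)

    @property
    def first_word(self) -> str:
        return self.tokens[0]


@dataclass
class FaceTrack:
    """Per-speaker facial landmark time series at a fixed frame rate.

    ``points`` maps landmark index -> (n_frames, 2) array of (x, y)
    coordinates in track units (mm for the 3-D coordinate set, pixels for
    the 2-D one). Frames where tracking failed are retained but flagged
    via ``success``.
    """

    speaker_id: str
    fps: float
    frame: np.ndarray  # (T,) int, consecutive from 0
    timestamp_ms: np.ndarray  # (T,) float
    success: np.ndarray  # (T,) bool
    points: dict[int, np.ndarray] = field(repr=False)

    def __post_init__(self):
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.timestamp_ms = np.asarray(self.timestamp_ms, dtype=float)
        self.success = np.asarray(self.success, dtype=bool)
        t = self.frame
        if t.size and not (np.all(np.diff(t) == 1) and t[0] == 0):
            raise ValidationError(
                f"frame indices must be consecutive integers from 0 "
                f"(track {self.speaker_id!r})"
            )
        dt = 1000.0 / self.fps
        expected = t * dt
        if t.size and np.max(np.abs(self.timestamp_ms - expected)) > dt:
            raise ValidationError(
                f"timestamps deviate from frame_index * {dt:.3f} ms by more "
                f"than one frame duration (track {self.speaker_id!r})"
            )
        for idx in LIP_QUAD_LANDMARKS:
            if idx not in self.points:
                raise ValidationError(f"landmark {idx} missing from track")
            self.points[idx] = np.asarray(self.points[idx], dtype=float)

    @property
    def n_frames(self) -> int:
        return int(self.frame.size)

    def quad_coords(self) -> np.ndarray:
        """(T, 4, 2) array of the outer-lip quad in p1..p4 order."""
        return np.stack([self.points[i] for i in LIP_QUAD_LANDMARKS], axis=1)


@dataclass
class AreaTrajectory:
    """Pre-acoustic lip-area epoch aligned to one utterance's onset.

    ``areas[k]`` is the lip area at frame ``k`` of the window; index 0 lies
    ``n_frames`` frame durations (3,000 ms at 30 fps for the default 90)
    before acoustic onset, index ``n_frames - 1`` is the last frame before
    onset. Frames that could not be measured (tracking dropouts, window
    extending before the start of the track) are NaN with
    ``missing_mask`` True.
    """

    utterance_id: str
    areas: np.ndarray  # (n_frames,) float, NaN where missing
    missing_mask: np.ndarray  # (n_frames,) bool
    fps: float = 30.0

    def __post_init__(self):
        self.areas = np.asarray(self.areas, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.areas.shape != self.missing_mask.shape:
            raise ValidationError("areas and missing_mask shapes differ")
        ok = ~self.missing_mask
        if np.any(self.areas[ok] < 0):
            raise ValidationError("negative lip area in epoch")

    @property
    def n_frames(self) -> int:
        return int(self.areas.size)

    def frame_offsets_ms(self) -> np.ndarray:
        """Signed time of each epoch frame relative to acoustic onset.

        Index ``n_frames - 1`` maps to one frame duration before onset.
        """
        n = self.n_frames
        return (np.arange(n) - n) * (1000.0 / self.fps)


def slice_frame_index(offset_ms: float, n_frames: int = 90, fps: float = 30.0) -> int:
    """Map a nominal slice offset (e.g. -3000, -500, 0 ms) to an epoch index.

    Offsets count back from acoustic onset; the epoch holds only frames
    strictly before onset, so the nominal 0-ms slice maps to the last
    pre-acoustic frame (index ``n_frames - 1``).
    """
    i = round((offset_ms + n_frames * 1000.0 / fps) * fps / 1000.0)
    if i < 0:
        raise ValidationError(f"slice offset {offset_ms} precedes the epoch window")
    return min(int(i), n_frames - 1)
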