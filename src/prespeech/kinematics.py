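"""Lip-area computation, pre-acoustic epoch extraction, and movement speed.

Lip area is measured on the quadrilateral of four outer-lip landmarks —
left corner (48), top center (51), right corner (54), bottom center (57),
taken clockwise from the left corner as p1..p4. The primary metric draws a
perimeter of line segments around the points, treats each segment as the
hypotenuse of an axis-aligned right triangle, and sums the four triangle
areas plus a residual central rectangle::

    A_i = |X_i − X_{i+1}| · |Y_i − Y_{i+1}| / 2     (i = 1..4, X_5 ≡ X_1)
    A_j = |X_1 − X_3| · |Y_2 − Y_4|
    area = A_1 + A_2 + A_3 + A_4 + A_j

For quads whose corners are the x-extrema and whose top/bottom points are
the y-extrema (the generic lip configuration) this equals
``2 · bounding_box − shoelace``: it systematically *over*-states the true
polygon area, but inference only needs within-speaker contrasts, which a
monotone inflation leaves intact. :func:`shoelace_area` (the surveyor's
formula) is exposed as an explicitly non-default alternative and as the
oracle for property tests. Because both formulas take absolute values,
the metric is indifferent to whether y grows upward or downward.

Epochs are the ``n_frames`` (default 90, i.e. 3,000 ms at 30 fps) frames
ending at the last frame strictly before acoustic onset. Tracking dropouts
are linearly interpolated across runs of up to ``max_fill`` frames; longer
runs stay missing and exclude the utterance from the affected slices.

Maximum lip movement speed takes the ``window`` (default 15) final
first-differences of the epoch, scales each by fps so the units are
area/s (mm²/s for the 3-D coordinate set), and keeps the value of largest
absolute magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from prespeech.core import AreaTrajectory, FaceTrack
from prespeech.errors import EpochRangeError, InsufficientDataError, ValidationError


def _as_quad(quad) -> np.ndarray:
    q = np.asarray(quad, dtype=float)
    if q.shape[-2:] != (4, 2):
        raise ValidationError(f"expected (..., 4, 2) quad coordinates, got {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValidationError("non-finite coordinate in lip quad")
    return q


def lip_area(quad) -> float | np.ndarray:
    """Primary lip-area metric (right triangles + residual rectangle).

    ``quad`` is (..., 4, 2): p1 left corner, p2 top center, p3 right
    corner, p4 bottom center. Broadcasts over leading axes; never
    negative.
    """
    q = _as_quad(quad)
    x, y = q[..., 0], q[..., 1]
    nxt = [1, 2, 3, 0]
    tri = 0.5 * np.abs(x - x[..., nxt]) * np.abs(y - y[..., nxt])
    rect = np.abs(x[..., 0] - x[..., 2]) * np.abs(y[..., 1] - y[..., 3])
    return tri.sum(axis=-1) + rect


def shoelace_area(quad) -> float | np.ndarray:
    """Absolute polygon area of p1..p4 by the surveyor's formula."""
    q = _as_quad(quad)
    x, y = q[..., 0], q[..., 1]
    nxt = [1, 2, 3, 0]
    return 0.5 * np.abs((x * y[..., nxt] - x[..., nxt] * y).sum(axis=-1))


def anchor_index(timestamps_ms: np.ndarray, onset_ms: float) -> int:
    """Index of the last frame strictly before the acoustic onset.

    A microsecond tolerance keeps a frame that lands numerically *on* the
    onset (e.g. frame 90 of a 30-fps track for a 3,000-ms onset) out of
    the pre-acoustic window regardless of floating-point representation.
    """
    return int(np.searchsorted(timestamps_ms, onset_ms - 1e-6, side="left")) - 1


@dataclass(frozen=True)
class SpeedSummary:
    """Maximum absolute lip-area change rate in the final epoch window."""

    max_speed: float  # area units^2 per second
    argmax_frame: int  # epoch index of the step's later frame


def extract_epoch(
    track: FaceTrack,
    onset_ms: float,
    utterance_id: str = "",
    n_frames: int = 90,
    fill_policy: str = "interpolate",
    max_fill: int = 3,
    area_fn=lip_area,
) -> AreaTrajectory:
    """Extract the pre-acoustic lip-area epoch for one utterance.

    The anchor is the last frame whose timestamp is strictly before
    ``onset_ms`` (half-open window convention); the epoch is the
    ``n_frames`` frames ending at the anchor. Frames before the start of
    the track, and unsuccessful frames not bridged by the fill policy,
    are NaN with ``missing_mask`` set.

    ``fill_policy``: ``"interpolate"`` bridges runs of up to ``max_fill``
    consecutive unsuccessful frames linearly (they stay flagged in
    ``missing_mask``); ``"exclude"`` leaves all unsuccessful frames
    missing.
    """
    if fill_policy not in ("interpolate", "exclude"):
        raise ValueError(f"unknown fill_policy {fill_policy!r}")
    anchor = anchor_index(track.timestamp_ms, onset_ms)
    if anchor < 0:
        raise EpochRangeError(
            f"onset {onset_ms} ms precedes the first track frame"
        )
    lo = anchor - n_frames + 1
    pad = max(0, -lo)
    sel = slice(max(lo, 0), anchor + 1)

    quads = track.quad_coords()[sel]
    areas_obs = np.asarray(area_fn(quads), dtype=float)
    good = track.success[sel].copy()

    areas = np.full(n_frames, np.nan)
    missing = np.ones(n_frames, dtype=bool)
    areas[pad:] = np.where(good, areas_obs, np.nan)
    missing[pad:] = ~good

    if fill_policy == "interpolate":
        areas = _fill_short_runs(areas, max_fill, pad)
    return AreaTrajectory(
        utterance_id=utterance_id,
        areas=areas,
        missing_mask=missing,
        fps=track.fps,
    )


def _fill_short_runs(areas: np.ndarray, max_fill: int, pad: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_fill."""
    out = areas.copy()
    n = out.size
    valid = np.flatnonzero(~np.isnan(out))
    if valid.size < 2:
        return out
    i = pad
    while i < n:
        if np.isnan(out[i]):
            j = i
            while j < n and np.isnan(out[j]):
                j += 1
            run = j - i
            if run <= max_fill and i > pad and j < n and not np.isnan(out[i - 1]):
                xs = np.arange(i, j)
                out[i:j] = np.interp(xs, [i - 1, j], [out[i - 1], out[j]])
            i = j
        else:
            i += 1
    return out


def max_speed(
    traj: AreaTrajectory, fps: float | None = None, window: int = 15
) -> SpeedSummary:
    """Maximum absolute lip-area change rate over the final window.

    Uses the ``window`` first-differences ending at the last epoch frame
    (frames ``n−window−1 .. n−1``), each scaled by fps to area-units/s.
    Missing frames inside the window make the statistic undefined.
    """
    fps = traj.fps if fps is None else fps
    n = traj.n_frames
    if n < window + 1:
        raise InsufficientDataError(
            f"trajectory length {n} < window + 1 = {window + 1}"
        )
    tail = traj.areas[n - window - 1 :]
    if np.any(np.isnan(tail)):
        raise InsufficientDataError(
            "missing frames in the speed window; apply a fill policy upstream"
        )
    speeds = np.diff(tail) * fps
    k = int(np.argmax(np.abs(speeds)))
    return SpeedSummary(
        max_speed=float(np.abs(speeds[k])),
        argmax_frame=n - window + k,
    )
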