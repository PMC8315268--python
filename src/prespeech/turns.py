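"""Utterance typing and floor transfer offsets for dyadic conversation.

For each utterance the *reference* is the most recently initiated prior
utterance — the one with the latest strictly earlier acoustic onset —
whether or not that utterance has already ended. Typing rules:

- no reference at all -> ``initial`` (first utterance of the conversation);
- reference by the same speaker -> ``restart``;
- reference by the other speaker, but the reference's own onset fell
  within 500 ms after an initiation by the current speaker -> ``restart``
  (the current speaker is resuming an utterance the partner barged in on);
- otherwise a *response*, with floor transfer offset
  ``fto = onset_curr − offset_reference`` and subtype

  - ``gap`` — fto > 0 (a zero fto counts as a zero-length gap),
  - ``between_overlap`` — starts inside the reference but ends after it,
  - ``within_overlap`` — lies entirely inside the reference's acoustic span.

Restarts and the initial utterance are excluded from every analysis set;
floor transfer offsets are summarized over gaps and between-overlaps only
(a within-overlap's fto is measured to the reference's *end* even though
its timing target is a closure mid-utterance, so it can be misleadingly
negative — e.g. a backchannel inside a 100-second turn gets fto ≈ −99 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from prespeech.core import UtteranceRecord
from prespeech.errors import (
    EmptySetError,
    InsufficientDataError,
    TieBreakError,
    ValidationError,
)

RESTART_WINDOW_MS = 500

RESPONSE_TYPES = ("gap", "between_overlap", "within_overlap")
ALL_TYPES = ("initial", "restart") + RESPONSE_TYPES


@dataclass(frozen=True)
class TypedUtterance:
    """An utterance plus its turn-exchange type and derived predictors."""

    record: UtteranceRecord
    utterance_type: str
    fto_ms: int | None  # None for initial / restart
    word_count: int
    first_word: str

    @property
    def is_retained(self) -> bool:
        """Whether the utterance enters the analysis set."""
        return self.utterance_type in RESPONSE_TYPES


def classify_utterances(
    records: list[UtteranceRecord], tie_break: str = "error"
) -> list[TypedUtterance]:
    """Type every utterance of a two-speaker conversation.

    ``records`` may be in any order; classification sorts stably by onset.
    ``tie_break`` controls behaviour when two utterances share an onset:
    ``"error"`` (default) raises; ``"speaker"`` breaks ties by speaker id
    so results stay deterministic.
    """
    speakers = sorted({r.speaker_id for r in records})
    if len(speakers) > 2:
        raise ValidationError(f"expected at most 2 speakers, got {speakers}")

    order = sorted(range(len(records)), key=lambda i: (records[i].onset_ms, i))
    onsets = [records[i].onset_ms for i in order]
    if len(set(onsets)) != len(onsets):
        if tie_break == "error":
            dup = [o for o in onsets if onsets.count(o) > 1][0]
            raise TieBreakError(
                f"two utterances share onset {dup} ms and tie_break='error'"
            )
        if tie_break == "speaker":
            order = sorted(
                range(len(records)),
                key=lambda i: (records[i].onset_ms, records[i].speaker_id, i),
            )
        else:
            raise ValueError(f"unknown tie_break policy {tie_break!r}")

    typed_by_index: dict[int, TypedUtterance] = {}
    seen: list[UtteranceRecord] = []  # in onset order
    for pos, idx in enumerate(order):
        cur = records[idx]
        utype, fto = _classify_one(cur, seen)
        typed_by_index[idx] = TypedUtterance(
            record=cur,
            utterance_type=utype,
            fto_ms=fto,
            word_count=cur.word_count,
            first_word=cur.first_word,
        )
        seen.append(cur)
    return [typed_by_index[i] for i in range(len(records))]


def _classify_one(
    cur: UtteranceRecord, prior: list[UtteranceRecord]
) -> tuple[str, int | None]:
    """Classify ``cur`` given all prior utterances in onset order."""
    ref = None
    for p in prior:  # prior is onset-sorted; last strictly-earlier onset wins
        if p.onset_ms < cur.onset_ms:
            ref = p
    if ref is None:
        return "initial", None
    if ref.speaker_id == cur.speaker_id:
        return "restart", None
    # 500-ms rule: the partner's reference utterance itself started within
    # 500 ms after this speaker's own most recent initiation.
    own_prev = None
    for p in prior:
        if p.speaker_id == cur.speaker_id and p.onset_ms < ref.onset_ms:
            own_prev = p
    if own_prev is not None and ref.onset_ms - own_prev.onset_ms <= RESTART_WINDOW_MS:
        return "restart", None

    fto = cur.onset_ms - ref.offset_ms
    if fto >= 0:
        return "gap", fto  # fto == 0: zero-length gap, still non-overlapping
    if cur.offset_ms > ref.offset_ms:
        return "between_overlap", fto
    return "within_overlap", fto


def response_type_proportions(typed: list[TypedUtterance]) -> dict[str, float]:
    """Proportions of gap / between-overlap / within-overlap among retained
    (non-restart, non-initial) utterances; sums to 1."""
    retained = [t for t in typed if t.is_retained]
    if not typed:
        raise EmptySetError("no utterances supplied")
    if not retained:
        raise EmptySetError("no retained utterances (all restarts/initials)")
    n = len(retained)
    return {
        t: sum(1 for u in retained if u.utterance_type == t) / n
        for t in RESPONSE_TYPES
    }


def fto_summary(
    typed: list[TypedUtterance], bins: int | np.ndarray = 20
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Mean, sample SD (n−1) and histogram of floor transfer offsets.

    Restricted to gaps and between-overlaps: within-overlaps are excluded
    because their nominal timing target is a mid-utterance closure, not the
    reference's acoustic offset.
    """
    ftos = np.array(
        [
            t.fto_ms
            for t in typed
            if t.utterance_type in ("gap", "between_overlap")
        ],
        dtype=float,
    )
    if ftos.size < 2:
        raise InsufficientDataError(
            f"need >=2 gap/between-overlap utterances, got {ftos.size}"
        )
    counts, edges = np.histogram(ftos, bins=bins)
    return float(np.mean(ftos)), float(np.std(ftos, ddof=1)), (counts, edges)
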