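"""Synthetic dyadic conversations with known anticipatory-posture truth.

The generator emits, for each simulated dyad, an utterance-tier annotation
table and one OpenFace-layout landmark track per speaker, plus a ground-
truth sidecar — the same shapes the pipeline reads from a real corpus —
so the full pipeline is testable end to end without the access-restricted
source recordings.

Behavioural model (see docs/methods.md for parameter rationale):

- Two speakers alternate; occasional same-speaker *restarts* (default 10%)
  exercise the exclusion path, and short backchannels are injected inside
  long partner turns to produce within-overlaps. Floor transfer offsets
  for floor exchanges are drawn from a single normal distribution; whether
  an exchange is a gap or a between-overlap *emerges from the draw's
  sign*, so the planted gap/between split equals ``Phi(mean/sd)`` of the
  retained mass. :meth:`SimConfig.from_proportions` inverts this to hit a
  requested (gap, between, within) triple.
- Each speaker's lip-area signal rests at a baseline ``A0`` plus a
  speaker-level intercept, with AR(1) noise. Ahead of a *labially
  constrained* utterance the deterministic signal ramps linearly down to
  the constrained target ``A1 = A0 − posture_depth`` over the utterance's
  *lead time* ``lead(wc) = clip(Lmax · exp(−kappa·(wc−1)), min_lead, Lmax)``
  — long leads for short utterances, decaying with word count, with a
  floor representing the irreducible articulatory-to-acoustic lag.
  Unconstrained utterances stay at baseline. First-word intercepts and a
  speaker-level log10 word-count slope are added over the 3-s pre-onset
  window so the slice models' crossed random structure has real variance
  to estimate.
- Landmarks are synthesized as a diamond whose vertical half-extent is
  solved so that the *primary* (triangles + rectangle) area formula
  applied to landmarks 48/51/54/57 reproduces the planted area exactly.

A posture ramp needs ``lead`` ms of lip availability before onset; when a
drawn onset would start the ramp inside the speaker's own previous
utterance, the scheduler defers the onset (``enforce_feasibility=True``,
the default) or, with enforcement off, collects the offenders and raises
:class:`~prespeech.errors.FeasibilityError`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import norm

from prespeech.core import FaceTrack, UtteranceRecord, slice_frame_index
from prespeech.errors import FeasibilityError, ValidationError
from prespeech.io import write_openface_csv, write_utterance_tier
from prespeech.kinematics import anchor_index
from prespeech.labial import PronLexicon, code_constraint
from prespeech.slices import SLICE_OFFSETS

#: (word, relative frequency) — modelled on the observed one-word response
#: vocabulary plus common utterance-initial words; labial-constraint labels
#: are derived from the built-in lexicon so planted labels and pipeline
#: coding agree by construction.
DEFAULT_VOCABULARY: tuple[tuple[str, float], ...] = (
    ("yeah", 37), ("alright", 13), ("right", 9), ("no", 8), ("yep", 5),
    ("yes", 4), ("really", 3), ("so", 2), ("excellent", 1), ("mmhmm", 2),
    ("next", 1), ("nice", 1), ("oh", 4), ("ok", 4), ("thanks", 1),
    ("that's", 5), ("very", 1), ("well", 6), ("what", 5), ("which", 2),
    ("I", 20), ("but", 4), ("the", 6), ("we", 3), ("you", 4), ("it", 6),
    ("and", 7), ("this", 4), ("he", 4), ("she", 3), ("do", 1), ("maybe", 1),
    ("actually", 2), ("good", 1), ("sure", 1), ("okay", 3), ("when", 1),
    ("there", 3), ("they", 4), ("true", 1), ("not", 2), ("one", 1),
)

_FILLERS = ("and", "then", "it", "was", "the", "of", "that", "to", "this", "not")

#: Speaker pairing scheme: 6 speakers over 8 dyads (multiplicities 2/3/3/2/2/3,
#: mirroring a small conversation-database roster).
DEFAULT_PAIRINGS = (
    ("P1", "P2"), ("P1", "P3"), ("P2", "P3"), ("P2", "P6"),
    ("P3", "P6"), ("P4", "P5"), ("P4", "P6"), ("P5", "P6"),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic corpus (defaults = the conditions
    the recovery and calibration analyses run under)."""

    n_dyads: int = 8
    utterances_per_dyad: int = 60
    fps: float = 30.0
    # timing
    fto_mean_ms: float = 250.0
    fto_sd_ms: float = 900.0
    p_within: float = 0.30
    p_restart: float = 0.10
    dur_base_ms: float = 350.0
    dur_per_word_ms: float = 450.0
    # content
    wc_lognorm_mu: float = 0.7
    wc_lognorm_sigma: float = 1.2
    wc_max: int = 40
    vocabulary: tuple[tuple[str, float], ...] = DEFAULT_VOCABULARY
    # posture model
    baseline_area: float = 320.0  # A0, mm^2
    posture_depth: float = 100.0  # A0 − A1, mm^2 (0 = null, no posture)
    max_lead_ms: float = 3000.0  # Lmax
    lead_decay: float = float(np.log(3.0) / 2.0)  # kappa; lead(3) = 1000 ms
    min_lead_ms: float = 250.0  # articulatory-to-acoustic lag floor
    # hold A1 during constrained speech (off by default: the held deficit
    # bleeds into neighbouring utterances' pre-onset windows and biases the
    # planted contrast; epochs never look past their own onset anyway)
    speech_hold: bool = False
    # random effects and noise
    speaker_intercept_sd: float = 30.0
    speaker_slope_sd: float = 15.0
    word_intercept_sd: float = 12.0
    ar_rho: float = 0.8
    ar_innovation_sd: float = 10.8  # stationary sd = 18 mm^2
    speaker_noise_log_sd: float = 0.25  # speaker-level tracking-noise scale
    dropout_rate: float = 0.0  # per-frame tracking failure probability
    # scheduling
    enforce_feasibility: bool = True
    pairings: tuple[tuple[str, str], ...] = DEFAULT_PAIRINGS

    def __post_init__(self):
        if self.posture_depth < 0 or self.posture_depth > self.baseline_area:
            raise ValidationError("require 0 <= posture_depth <= baseline_area")
        if not (0 < self.max_lead_ms <= 3000):
            raise ValidationError("max_lead_ms must lie in (0, 3000]")
        if not 0 <= self.p_within < 1:
            raise ValidationError("p_within must lie in [0, 1)")

    @classmethod
    def from_proportions(
        cls, p_gap: float, p_between: float, p_within: float,
        fto_sd_ms: float = 900.0, **kwargs
    ) -> "SimConfig":
        """Solve the FTO-normal mean so the planted (gap, between, within)
        proportions hit the requested triple."""
        total = p_gap + p_between + p_within
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("proportions must sum to 1")
        mean = fto_sd_ms * norm.ppf(p_gap / (p_gap + p_between))
        return cls(
            fto_mean_ms=float(mean), fto_sd_ms=fto_sd_ms, p_within=p_within,
            **kwargs,
        )

    @property
    def planted_proportions(self) -> dict[str, float]:
        """Expected response-type proportions implied by the config."""
        p_gap_given_fx = float(norm.cdf(self.fto_mean_ms / self.fto_sd_ms))
        return {
            "gap": (1 - self.p_within) * p_gap_given_fx,
            "between_overlap": (1 - self.p_within) * (1 - p_gap_given_fx),
            "within_overlap": self.p_within,
        }

    def lead_ms(self, word_count: int) -> float:
        """Effective posture lead time for a constrained utterance."""
        raw = self.max_lead_ms * np.exp(-self.lead_decay * (word_count - 1))
        return float(np.clip(raw, self.min_lead_ms, self.max_lead_ms))


def vocabulary_labels(
    vocabulary=DEFAULT_VOCABULARY, lexicon: PronLexicon | None = None
) -> dict[str, bool]:
    """word -> is-labially-constrained map for the generator vocabulary."""
    lexicon = lexicon or PronLexicon.builtin()
    return {
        w: code_constraint(w, lexicon).value == "constrained"
        for w, _ in vocabulary
    }


def planted_effect_surface(
    config: SimConfig, offsets=SLICE_OFFSETS, word_counts=tuple(range(1, 13))
) -> pd.DataFrame:
    """Closed-form expected (unconstrained − constrained) area difference at
    each slice offset x word count, from the planted ramp geometry."""
    rows = []
    for wc in word_counts:
        lead = config.lead_ms(wc)
        for off in offsets:
            frac = 1.0 + off / lead  # off <= 0
            rows.append(
                {
                    "offset_ms": off,
                    "word_count": wc,
                    "effect": config.posture_depth * max(0.0, frac),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scheduling


def _draw_word_count(rng, config) -> int:
    extra = int(np.exp(rng.normal(config.wc_lognorm_mu, config.wc_lognorm_sigma)))
    return min(1 + extra, config.wc_max)


def _duration(rng, config, wc: int) -> float:
    return max(
        250.0,
        config.dur_base_ms + config.dur_per_word_ms * wc + rng.uniform(-100, 200),
    )


class _Scheduler:
    """Builds one dyad's utterance sequence."""

    def __init__(self, config: SimConfig, rng, labels: dict[str, bool], dyad_id: str):
        self.c = config
        self.rng = rng
        self.labels = labels
        self.dyad_id = dyad_id
        words, weights = zip(*config.vocabulary)
        self.words = list(words)
        self.wp = np.array(weights, float) / sum(weights)
        unc = [i for i, w in enumerate(words) if not labels[w]]
        self.unc_idx = unc
        self.unc_p = self.wp[unc] / self.wp[unc].sum()
        self.offenders: list[tuple[str, int]] = []
        # Every backchannel costs one excluded floor-taking restart, so the
        # per-utterance hosting probability h must be solved from the slot
        # accounting to make within-overlaps a fraction p_within of the
        # *retained* utterances: with N slots, D=1 initial, restart rate r,
        # B backchannels satisfy B = p_w (N(1-r) - D) / (1 + p_w (1-2r)).
        n_slots = config.utterances_per_dyad
        b = (
            config.p_within
            * (n_slots * (1 - config.p_restart) - 1)
            / (1 + config.p_within * (1 - 2 * config.p_restart))
        )
        self.host_p = min(max(b, 0.0) / max(n_slots - b, 1.0), 0.95)

    def _word(self, unconstrained_only: bool = False) -> str:
        if unconstrained_only:
            return self.words[self.rng.choice(self.unc_idx, p=self.unc_p)]
        return self.words[self.rng.choice(len(self.words), p=self.wp)]

    def _transcript(self, word: str, wc: int) -> str:
        fillers = [
            _FILLERS[self.rng.integers(len(_FILLERS))] for _ in range(wc - 1)
        ]
        return " ".join([word] + fillers)

    def _bc_duration(self, wc: int) -> float:
        # backchannels are short ("yeah", "oh right")
        return 300.0 + 150.0 * wc + self.rng.uniform(-50, 150)

    def run(self, speakers: tuple[str, str]) -> list[dict]:
        c, rng = self.c, self.rng
        last_on = {s: None for s in speakers}
        last_off = {s: None for s in speakers}
        utts: list[dict] = []
        pending_within = False  # the previous utterance was sized to host one
        post_within = False  # the previous utterance was a backchannel

        def other(s):
            return speakers[1] if s == speakers[0] else speakers[0]

        for k in range(c.utterances_per_dyad):
            will_host = False
            if k == 0:
                s = speakers[0]
                wc = _draw_word_count(rng, c)
                word = self._word()
                onset = 3500.0 + rng.uniform(0, 400)
                dur = _duration(rng, c, wc)
                will_host = rng.random() < self.host_p
                if will_host:
                    dur = max(dur, 2400.0)
                offset = onset + dur
                utype, fto = "initial", None
            elif post_within:
                # the backchanneler takes the floor once the host's turn
                # ends; by the reference rule this is a same-speaker restart
                post_within = False
                bc, host = utts[-1], utts[-2]
                s = bc["speaker"]
                wc = _draw_word_count(rng, c)
                word = self._word(unconstrained_only=True)
                onset = max(host["offset"], bc["offset"]) + rng.uniform(100, 400)
                dur = _duration(rng, c, wc)
                will_host = rng.random() < self.host_p
                if will_host:
                    dur = max(dur, 2400.0)
                offset = onset + dur
                utype, fto = "restart", None
            elif pending_within:
                # a short backchannel inside the (extended) partner turn,
                # preferentially placed late in the turn
                prev = utts[-1]
                s = other(prev["speaker"])
                wc = 1 if rng.random() < 0.75 else 2
                word = self._word()
                dur = self._bc_duration(wc)
                lo = prev["onset"] + 60
                if last_off[s] is not None:
                    lo = max(lo, last_off[s] + 60)
                hi = prev["offset"] - 50 - dur
                if lo <= hi:
                    onset = min(max(hi - rng.uniform(0, 200), lo), hi)
                    offset = onset + dur
                    if (
                        c.posture_depth > 0
                        and self.labels[word]
                        and last_off[s] is not None
                        and onset - c.lead_ms(wc) < last_off[s] + 30
                    ):
                        # no room to posture before a backchannel: a speaker
                        # in that position produces an unconstrained one
                        word = self._word(unconstrained_only=True)
                    utype = "within_overlap"
                    fto = onset - prev["offset"]
                    post_within = True
                else:
                    s, wc, word, onset, offset, utype, fto = self._floor_exchange(
                        utts, last_on, last_off, other, k
                    )
                    will_host = rng.random() < self.host_p
                    if will_host:
                        offset = onset + max(offset - onset, 2400.0)
            elif rng.random() < c.p_restart:
                prev = utts[-1]
                s = prev["speaker"]
                wc = _draw_word_count(rng, c)
                word = self._word(unconstrained_only=True)
                onset = prev["offset"] + rng.uniform(150, 450)
                dur = _duration(rng, c, wc)
                will_host = rng.random() < self.host_p
                if will_host:
                    dur = max(dur, 2400.0)
                offset = onset + dur
                utype, fto = "restart", None
            else:
                s, wc, word, onset, offset, utype, fto = self._floor_exchange(
                    utts, last_on, last_off, other, k
                )
                will_host = rng.random() < self.host_p
                if will_host:
                    offset = onset + max(offset - onset, 2400.0)
            # the 500-ms restart rule can still fire when the reference
            # utterance began hot on this speaker's own heels
            if utype not in ("initial", "restart"):
                prev = utts[-1]
                if last_on[s] is not None and prev["onset"] - last_on[s] <= 500:
                    utype, fto = "restart", None
            pending_within = will_host and utype != "within_overlap"

            onset_i, offset_i = int(round(onset)), int(round(offset))
            if offset_i <= onset_i:
                offset_i = onset_i + 1
            if utype not in ("initial", "restart"):
                # re-derive the planted type from the *rounded* times the
                # classifier will actually see
                ref_off = int(utts[-1]["offset"])
                fto = onset_i - ref_off
                if fto >= 0:
                    utype = "gap"
                elif offset_i > ref_off:
                    utype = "between_overlap"
                else:
                    utype = "within_overlap"
            constrained = self.labels[word] and utype != "restart"
            utts.append(
                {
                    "index": k,
                    "speaker": s,
                    "onset": float(onset_i),
                    "offset": float(offset_i),
                    "word": word,
                    "word_count": wc,
                    "transcript": self._transcript(word, wc),
                    "constrained": bool(constrained),
                    "lead_ms": self.c.lead_ms(wc) if constrained else 0.0,
                    "planted_type": utype,
                    "planted_fto_ms": None if fto is None else float(fto),
                }
            )
            last_on[s] = onset_i
            last_off[s] = offset_i
        return utts

    def _floor_exchange(self, utts, last_on, last_off, other, k):
        """An ordinary floor exchange: FTO drawn from the config normal;
        gap vs between-overlap emerges from the realized sign."""
        c, rng = self.c, self.rng
        prev = utts[-1]
        s = other(prev["speaker"])
        wc = _draw_word_count(rng, c)
        word = self._word()
        # a ramp must fit before the onset only when there is a ramp at all
        constrained = self.labels[word] and c.posture_depth > 0
        lead = c.lead_ms(wc) if constrained else 0.0
        onset = prev["offset"] + rng.normal(c.fto_mean_ms, c.fto_sd_ms)
        onset = max(onset, prev["onset"] + 60)
        if last_off[s] is not None:
            onset = max(onset, last_off[s] + 60)
            if constrained and onset - lead < last_off[s] + 30:
                if c.enforce_feasibility:
                    # defer: the speaker starts once the lips had time to
                    # reach the posture
                    onset = last_off[s] + lead + 30
                else:
                    self.offenders.append((self.dyad_id, k))
        offset = onset + _duration(rng, c, wc)
        fto = onset - prev["offset"]
        if fto > 0:
            utype = "gap"
        elif offset > prev["offset"]:
            utype = "between_overlap"
        else:
            utype = "within_overlap"
        return s, wc, word, onset, offset, utype, fto


# ---------------------------------------------------------------------------
# landmark synthesis

_OUTER_ANGLES = np.deg2rad([180, 150, 120, 90, 60, 30, 0, -30, -60, -90, -120, -150])
_INNER_ANGLES = np.deg2rad([180, 135, 90, 45, 0, -45, -90, -135])
_HALF_WIDTH = 25.0  # mm; fixed lip half-width so area maps to height alone


def _areas_to_track(
    speaker_id: str, areas: np.ndarray, fps: float, success: np.ndarray,
    center=(0.0, 50.0),
) -> FaceTrack:
    """Landmarks whose 48/51/54/57 diamond gives back ``areas`` under the
    primary (triangles + rectangle) formula: area = 6 · w_half · h_half."""
    n = areas.size
    h = areas / (6.0 * _HALF_WIDTH)
    cx, cy = center
    points: dict[int, np.ndarray] = {}
    for j, ang in enumerate(_OUTER_ANGLES):
        idx = 48 + j
        points[idx] = np.column_stack(
            [cx + _HALF_WIDTH * np.cos(ang) * np.ones(n), cy - h * np.sin(ang)]
        )
    for j, ang in enumerate(_INNER_ANGLES):
        idx = 60 + j
        points[idx] = np.column_stack(
            [
                cx + 0.6 * _HALF_WIDTH * np.cos(ang) * np.ones(n),
                cy - 0.6 * h * np.sin(ang),
            ]
        )
    return FaceTrack(
        speaker_id=speaker_id,
        fps=fps,
        frame=np.arange(n),
        timestamp_ms=np.arange(n) * (1000.0 / fps),
        success=success,
        points=points,
    )


def _deterministic_area(
    times: np.ndarray, own_utts: list[dict], config: SimConfig,
    u_i: float, s_i: float, word_effects: dict[str, float],
) -> np.ndarray:
    """Noise-free area signal for one speaker over frame times (ms)."""
    det = np.full(times.size, config.baseline_area + u_i)
    window = 3000.0
    fade = 500.0
    for u in own_utts:
        onset, offset = u["onset"], u["offset"]
        eff = word_effects.get(u["word"], 0.0) + s_i * np.log10(u["word_count"])
        if eff != 0.0:
            m = (times >= onset - window) & (times < onset)
            det[m] += eff * np.clip((times[m] - (onset - window)) / fade, 0, 1)
        if u["constrained"] and config.posture_depth > 0:
            lead = u["lead_ms"]
            t0 = onset - lead
            m1 = (times >= t0) & (times < onset)
            det[m1] -= config.posture_depth * (times[m1] - t0) / lead
            if config.speech_hold:
                m2 = (times >= onset) & (times < offset)
                det[m2] -= config.posture_depth
                m3 = (times >= offset) & (times < offset + 300)
                det[m3] -= config.posture_depth * (1 - (times[m3] - offset) / 300)
    return det


# ---------------------------------------------------------------------------
# top-level generation


@dataclass
class Conversation:
    dyad_id: str
    speakers: tuple[str, str]
    records: list[UtteranceRecord]
    tracks: dict[str, FaceTrack]
    truth: dict


@dataclass
class Corpus:
    config: SimConfig
    seed: int
    dyads: list[Conversation]
    speaker_effects: dict[str, dict[str, float]]
    word_effects: dict[str, float]


def _draw_speaker_effects(rng, config: SimConfig) -> dict[str, float]:
    return {
        "intercept": float(rng.normal(0, config.speaker_intercept_sd)),
        "slope": float(rng.normal(0, config.speaker_slope_sd)),
        "noise_scale": float(
            np.exp(rng.normal(0, config.speaker_noise_log_sd))
        ),
    }


def generate_conversation(
    config: SimConfig,
    seed,
    dyad_id: str = "dyad01",
    speakers: tuple[str, str] = ("A", "B"),
    speaker_effects: dict[str, dict[str, float]] | None = None,
    word_effects: dict[str, float] | None = None,
    labels: dict[str, bool] | None = None,
) -> Conversation:
    """Generate one dyad: annotation records, a track per speaker, truth.

    ``seed`` may be an int or a numpy Generator. Speaker/word effects are
    drawn here unless supplied (a corpus draws them once and shares them
    across dyads).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = labels or vocabulary_labels(config.vocabulary)
    if speaker_effects is None:
        speaker_effects = {s: _draw_speaker_effects(rng, config) for s in speakers}
    if word_effects is None:
        word_effects = {
            w: rng.normal(0, config.word_intercept_sd) for w, _ in config.vocabulary
        }

    sched = _Scheduler(config, rng, labels, dyad_id)
    utts = sched.run(speakers)
    if sched.offenders:
        raise FeasibilityError(sched.offenders)

    records = [
        UtteranceRecord(u["speaker"], int(u["onset"]), int(u["offset"]), u["transcript"])
        for u in utts
    ]

    dt = 1000.0 / config.fps
    tracks: dict[str, FaceTrack] = {}
    planted: dict[str, dict] = {}
    for s in speakers:
        own = [u for u in utts if u["speaker"] == s]
        t_end = max(u["offset"] for u in own) + 600 if own else 1000
        n_fr = int(np.ceil(t_end / dt)) + 1
        times = np.arange(n_fr) * dt
        det = _deterministic_area(
            times, own, config,
            speaker_effects[s]["intercept"], speaker_effects[s]["slope"],
            word_effects,
        )
        if config.ar_innovation_sd > 0:
            inn_sd = config.ar_innovation_sd * speaker_effects[s]["noise_scale"]
            eta = rng.normal(0, inn_sd, n_fr)
            sd_stat = inn_sd / np.sqrt(1 - config.ar_rho**2)
            e0 = rng.normal(0, sd_stat)
            noise = sps.lfilter(
                [1.0], [1.0, -config.ar_rho], eta, zi=np.array([config.ar_rho * e0])
            )[0]
        else:
            noise = np.zeros(n_fr)
        areas = np.clip(det + noise, 1.0, None)
        success = rng.random(n_fr) >= config.dropout_rate
        tracks[s] = _areas_to_track(s, areas, config.fps, success)

        # planted per-slice deterministic areas for this speaker's utterances
        for u in own:
            anchor = anchor_index(times, u["onset"])
            slice_truth = {}
            for off in SLICE_OFFSETS:
                idx = anchor - 89 + slice_frame_index(off)
                if 0 <= idx < n_fr:
                    slice_truth[str(off)] = float(det[idx])
            planted[f"{dyad_id}:{u['index']}"] = {
                **{k: u[k] for k in (
                    "speaker", "onset", "offset", "word", "word_count",
                    "constrained", "lead_ms", "planted_type", "planted_fto_ms",
                )},
                "planted_slice_areas": slice_truth,
            }

    truth = {
        "dyad_id": dyad_id,
        "speakers": list(speakers),
        "speaker_effects": {s: speaker_effects[s] for s in speakers},
        "utterances": planted,
    }
    return Conversation(dyad_id, speakers, records, tracks, truth)


def generate_corpus(config: SimConfig, seed: int) -> Corpus:
    """Generate ``n_dyads`` conversations with shared speaker/word effects.

    Deterministic: the same (config, seed) reproduces the corpus exactly.
    """
    master = np.random.default_rng(np.random.SeedSequence(seed))
    labels = vocabulary_labels(config.vocabulary)
    speakers = sorted({s for pair in config.pairings for s in pair})
    speaker_effects = {s: _draw_speaker_effects(master, config) for s in speakers}
    word_effects = {
        w: master.normal(0, config.word_intercept_sd) for w, _ in config.vocabulary
    }
    dyads = []
    for d in range(config.n_dyads):
        pair = config.pairings[d % len(config.pairings)]
        conv = generate_conversation(
            config,
            master,
            dyad_id=f"dyad{d + 1:02d}",
            speakers=pair,
            speaker_effects=speaker_effects,
            word_effects=word_effects,
            labels=labels,
        )
        dyads.append(conv)
    return Corpus(config, seed, dyads, speaker_effects, word_effects)


def write_corpus(corpus: Corpus, out_dir) -> None:
    """Emit the corpus in the pipeline's external dialects.

    Layout: ``<out>/<dyad>/annotations.tsv`` + ``<out>/<dyad>/<spk>.csv``
    (OpenFace layout), plus a ``sim_truth.json`` sidecar at the root.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_all = {
        "seed": corpus.seed,
        "config": _config_json(corpus.config),
        "speaker_effects": corpus.speaker_effects,
        "word_effects": corpus.word_effects,
        "dyads": {},
    }
    for conv in corpus.dyads:
        ddir = out / conv.dyad_id
        ddir.mkdir(exist_ok=True)
        write_utterance_tier(conv.records, ddir / "annotations.tsv")
        for s, track in conv.tracks.items():
            write_openface_csv(track, ddir / f"{s}.csv")
        truth_all["dyads"][conv.dyad_id] = conv.truth
    with open(out / "sim_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_all, fh, indent=1, sort_keys=True)


def _config_json(config: SimConfig) -> dict:
    d = asdict(config)
    d["vocabulary"] = [list(v) for v in d["vocabulary"]]
    d["pairings"] = [list(p) for p in d["pairings"]]
    return d


def null_config(config: SimConfig | None = None) -> SimConfig:
    """The no-posture null: no constraint-associated area signal anywhere.

    Zeroes the posture depth *and* the first-word intercepts: labial
    constraint is a deterministic function of the first word, so any
    word-identity variation in lip area induces a corpus-level constraint
    contrast (a real confound, not a false positive — reference mixed-model
    software shows the same rejections on such corpora). The calibration
    null removes both sources.
    """
    return replace(
        config or SimConfig(), posture_depth=0.0, word_intercept_sd=0.0
    )
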