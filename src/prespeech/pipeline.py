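"""End-to-end orchestration: typing -> coding -> epoching -> slice models.

The in-memory entry point is :func:`analyze_corpus`, which takes parsed
dyads (annotation records + landmark tracks) and returns a
:class:`PipelineResult` bundle; :func:`run_pipeline` wraps it with file
I/O, a manifest (config hash + seed) and a run log, so a run is a pure
function of (inputs, RunConfig). Every exclusion — restart, initial,
missing or too-short track, out-of-lexicon first word — is counted and
logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from prespeech.errors import (
    EmptySetError,
    EpochRangeError,
    InsufficientDataError,
    StageError,
)
from prespeech.io import (
    epochs_to_table,
    read_openface_csv,
    read_utterance_tier,
)
from prespeech.kinematics import extract_epoch, max_speed
from prespeech.labial import PronLexicon, code_corpus, load_overrides
from prespeech.slices import (
    SLICE_OFFSETS,
    SliceModelResult,
    bootstrap_predictions,
    fit_all_slices,
    fit_speed_model,
    results_table,
)
from prespeech.turns import classify_utterances, fto_summary, response_type_proportions


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one pipeline run."""

    corpus_dir: str = ""
    out_dir: str = ""
    lexicon_path: str | None = None  # None -> built-in lexicon
    overrides_path: str | None = None
    slice_offsets: tuple[int, ...] = SLICE_OFFSETS
    alpha: float = 0.05
    bootstrap_B: int = 0  # 0 skips the prediction bands
    bootstrap_word_counts: tuple[int, ...] = (2, 8)
    seed: int = 0
    fill_policy: str = "interpolate"
    max_fill: int = 3
    coordinate_set: str = "3d_mm"
    tie_break: str = "error"
    n_frames: int = 90
    jn_df_mode: str = "pointwise"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All tables and fitted models of one run."""

    typed_table: pd.DataFrame
    epoch_table: pd.DataFrame
    slice_results: list[SliceModelResult]
    slice_table: pd.DataFrame
    speed_table: pd.DataFrame
    speed_result: SliceModelResult
    predictions: pd.DataFrame | None
    fto_mean_ms: float
    fto_sd_ms: float
    proportions: dict[str, float]
    exclusions: dict[str, int]
    log: list[str] = field(default_factory=list)


def analyze_corpus(
    dyads: list[tuple[str, list, dict]],
    lexicon: PronLexicon | None = None,
    overrides: dict[str, str] | None = None,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run the full analysis over parsed dyads.

    ``dyads`` is a list of (dyad_id, utterance records, {speaker: track}).
    """
    lexicon = lexicon or PronLexicon.builtin()
    log: list[str] = []
    exclusions = {"restart": 0, "initial": 0, "no_epoch": 0, "no_speed": 0}

    typed_all = []  # (dyad_id, index, TypedUtterance)
    for dyad_id, records, _tracks in dyads:
        try:
            typed = classify_utterances(records, tie_break=config.tie_break)
        except Exception as exc:  # surface the stage and record id
            raise StageError("typing", dyad_id, exc) from exc
        for k, t in enumerate(typed):
            typed_all.append((dyad_id, k, t))
            if t.utterance_type in ("restart", "initial"):
                exclusions[t.utterance_type] += 1

    flat_typed = [t for _, _, t in typed_all]
    if not any(t.is_retained for t in flat_typed):
        raise EmptySetError(
            "no analysable utterances: every utterance is a restart or initial"
        )
    proportions = response_type_proportions(flat_typed)
    fto_mean, fto_sd, _hist = fto_summary(flat_typed)
    log.append(
        f"typed {len(flat_typed)} utterances; retained "
        f"{sum(t.is_retained for t in flat_typed)} "
        f"(excluded {exclusions['restart']} restarts, "
        f"{exclusions['initial']} initials)"
    )

    coded = code_corpus(flat_typed, lexicon, overrides)
    label_by_id = {id(t): lab for t, lab in coded}

    track_by = {dyad_id: tracks for dyad_id, _, tracks in dyads}
    epochs, meta, speed_rows, typed_rows = [], [], [], []
    for dyad_id, k, t in typed_all:
        uid = f"{dyad_id}:{k}"
        label = label_by_id.get(id(t))
        typed_rows.append(
            {
                "utterance_id": uid,
                "speaker_id": t.record.speaker_id,
                "onset_ms": t.record.onset_ms,
                "offset_ms": t.record.offset_ms,
                "utterance_type": t.utterance_type,
                "fto_ms": t.fto_ms,
                "word_count": t.word_count,
                "first_word": t.first_word,
                "constraint": label.value if label else "",
            }
        )
        if label is None:
            continue
        track = track_by[dyad_id].get(t.record.speaker_id)
        if track is None:
            exclusions["no_epoch"] += 1
            continue
        try:
            epoch = extract_epoch(
                track,
                t.record.onset_ms,
                utterance_id=uid,
                n_frames=config.n_frames,
                fill_policy=config.fill_policy,
                max_fill=config.max_fill,
            )
        except EpochRangeError:
            exclusions["no_epoch"] += 1
            continue
        m = {
            "speaker_id": t.record.speaker_id,
            "word_count": t.word_count,
            "first_word": t.first_word.casefold(),
            "constraint": label.value,
            "utterance_type": t.utterance_type,
        }
        epochs.append(epoch)
        meta.append(m)
        try:
            sp = max_speed(epoch)
            speed_rows.append(
                {
                    "utterance_id": uid,
                    "speaker_id": m["speaker_id"],
                    "first_word": m["first_word"],
                    "word_count": m["word_count"],
                    "constraint": m["constraint"],
                    "max_speed": sp.max_speed,
                }
            )
        except InsufficientDataError:
            exclusions["no_speed"] += 1

    log.append(
        f"extracted {len(epochs)} epochs "
        f"({exclusions['no_epoch']} utterances without a usable window)"
    )
    epoch_table = epochs_to_table(epochs, meta)
    if epoch_table.empty:
        raise EmptySetError("no epochs could be extracted")

    slice_results = fit_all_slices(
        epoch_table,
        offsets=config.slice_offsets,
        alpha=config.alpha,
        jn_df_mode=config.jn_df_mode,
        n_frames=config.n_frames,
    )
    slice_table = results_table(slice_results)
    for r in slice_results:
        log.append(
            f"slice {r.offset_ms:+d} ms: n={r.n}, {r.random_structure}, "
            f"constraint beta={r.terms['constraint']['beta']:.2f} "
            f"(p={r.terms['constraint']['p']:.4f})"
        )

    speed_table = pd.DataFrame(speed_rows)
    speed_result = fit_speed_model(speed_table)
    log.append(
        f"speed model: {speed_result.random_structure}, word-count "
        f"beta={speed_result.terms['log10_word_count']['beta']:.2f}"
    )

    predictions = None
    if config.bootstrap_B > 0:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 17)))
        frames = []
        for r in slice_results:
            p = bootstrap_predictions(
                r,
                word_counts=config.bootstrap_word_counts,
                B=config.bootstrap_B,
                seed=rng,
            )
            p.insert(0, "offset_ms", r.offset_ms)
            frames.append(p)
        predictions = pd.concat(frames, ignore_index=True)

    return PipelineResult(
        typed_table=pd.DataFrame(typed_rows),
        epoch_table=epoch_table,
        slice_results=slice_results,
        slice_table=slice_table,
        speed_table=speed_table,
        speed_result=speed_result,
        predictions=predictions,
        fto_mean_ms=fto_mean,
        fto_sd_ms=fto_sd,
        proportions=proportions,
        exclusions=exclusions,
        log=log,
    )


def load_corpus_dir(corpus_dir, coordinate_set: str = "3d_mm"):
    """Read a corpus directory: one subdirectory per dyad holding
    ``annotations.tsv`` plus one OpenFace CSV per speaker."""
    corpus_dir = Path(corpus_dir)
    dyads = []
    for ddir in sorted(p for p in corpus_dir.iterdir() if p.is_dir()):
        ann = ddir / "annotations.tsv"
        if not ann.exists():
            continue
        records = read_utterance_tier(ann)
        tracks = {}
        for csv_path in sorted(ddir.glob("*.csv")):
            tracks[csv_path.stem] = read_openface_csv(
                csv_path, speaker_id=csv_path.stem, coordinate_set=coordinate_set
            )
        dyads.append((ddir.name, records, tracks))
    if not dyads:
        raise EmptySetError(f"no dyad subdirectories found under {corpus_dir}")
    return dyads


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based run: load, analyze, and write all result tables."""
    dyads = load_corpus_dir(config.corpus_dir, config.coordinate_set)
    lexicon = (
        PronLexicon.from_file(config.lexicon_path)
        if config.lexicon_path
        else PronLexicon.builtin()
    )
    overrides = (
        load_overrides(config.overrides_path) if config.overrides_path else None
    )
    result = analyze_corpus(dyads, lexicon, overrides, config)
    if config.out_dir:
        write_results(result, config)
    return result


def write_results(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.typed_table.to_csv(out / "typed_utterances.csv", index=False, lineterminator="\n")
    result.epoch_table.to_csv(out / "epochs.csv", index=False, lineterminator="\n")
    result.slice_table.to_csv(out / "slice_results.csv", index=False, lineterminator="\n")
    result.speed_table.to_csv(out / "speed_table.csv", index=False, lineterminator="\n")
    results_table([result.speed_result]).to_csv(
        out / "speed_model.csv", index=False, lineterminator="\n"
    )
    if result.predictions is not None:
        result.predictions.to_csv(out / "predictions.csv", index=False, lineterminator="\n")
    summary = {
        "fto_mean_ms": result.fto_mean_ms,
        "fto_sd_ms": result.fto_sd_ms,
        "proportions": result.proportions,
        "exclusions": result.exclusions,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest = {
        "config": json.loads(config.to_json()),
        "config_digest": config.digest,
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "run.log").write_text("\n".join(result.log) + "\n")
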