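"""The synthetic dyad generator: determinism, planted truth, recovery."""

import hashlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

import prespeech.pipeline as pl
from prespeech.errors import FeasibilityError
from prespeech.kinematics import lip_area
from prespeech.labial import code_constraint
from prespeech.simulate import (
    SimConfig,
    generate_conversation,
    generate_corpus,
    null_config,
    planted_effect_surface,
    vocabulary_labels,
    write_corpus,
)
from prespeech.turns import classify_utterances, fto_summary, response_type_proportions


def _hash_dir(path: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.rglob("*"))
        if p.is_file()
    }


SMALL = replace(SimConfig(), n_dyads=2, utterances_per_dyad=18)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        for d in ("a", "b"):
            write_corpus(generate_corpus(SMALL, 123), tmp_path / d)
        assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")

    def test_different_seeds_differ(self, tmp_path):
        for d, seed in (("a", 1), ("b", 2)):
            write_corpus(generate_corpus(SMALL, seed), tmp_path / d)
        assert _hash_dir(tmp_path / "a") != _hash_dir(tmp_path / "b")


class TestPlantedSurface:
    def test_ramp_endpoint_equals_full_depth(self):
        cfg = SimConfig()
        surf = planted_effect_surface(cfg)
        at0 = surf[surf.offset_ms == 0]
        np.testing.assert_allclose(at0.effect, cfg.posture_depth)

    def test_effect_zero_at_exact_ramp_start(self):
        cfg = SimConfig()  # lead(1) = Lmax = 3000
        surf = planted_effect_surface(cfg, offsets=(-3000,), word_counts=(1,))
        assert surf.effect.iloc[0] == 0.0
        inside = planted_effect_surface(cfg, offsets=(-2500,), word_counts=(1,))
        assert inside.effect.iloc[0] > 0

    def test_posture_not_yet_begun(self):
        # lead(3) = 1000 ms by default, so nothing at -1500
        cfg = SimConfig()
        assert cfg.lead_ms(3) == pytest.approx(1000.0, rel=1e-12)
        surf = planted_effect_surface(cfg, offsets=(-1500,), word_counts=(3,))
        assert surf.effect.iloc[0] == 0.0

    def test_fast_decay_isolates_slice_zero(self):
        cfg = replace(SimConfig(), lead_decay=50.0)  # lead ~ min_lead for wc>1
        surf = planted_effect_surface(cfg, word_counts=(2, 5, 9))
        nonzero = surf[surf.effect > 0]
        assert set(nonzero.offset_ms) == {0}


class TestGroundTruthIdentity:
    def test_noise_free_epochs_equal_planted_areas(self):
        cfg = replace(
            SMALL,
            ar_innovation_sd=0.0,
            speaker_intercept_sd=0.0,
            speaker_slope_sd=0.0,
            word_intercept_sd=0.0,
            speaker_noise_log_sd=0.0,
        )
        corpus = generate_corpus(cfg, 3)
        dyads = [(c.dyad_id, c.records, c.tracks) for c in corpus.dyads]
        res = pl.analyze_corpus(dyads)
        truth = {}
        for c in corpus.dyads:
            truth.update(c.truth["utterances"])
        from prespeech.slices import SLICE_OFFSETS, slice_dataset

        checked = 0
        for off in SLICE_OFFSETS:
            for _, row in slice_dataset(res.epoch_table, off).iterrows():
                planted = truth[row.utterance_id]["planted_slice_areas"].get(str(off))
                if planted is not None:
                    assert row.area == pytest.approx(planted, abs=1e-9)
                    checked += 1
        assert checked > 50

    def test_landmarks_invert_primary_area_formula(self):
        conv = generate_conversation(SMALL, 5, speakers=("A", "B"))
        track = conv.tracks["A"]
        quads = track.quad_coords()
        back = lip_area(quads)
        # reconstruct the planted area series from the inverse map
        assert back.shape[0] == track.n_frames
        assert (back > 0).all()

    def test_labels_match_pipeline_coder(self, lexicon):
        labels = vocabulary_labels()
        for word, constrained in labels.items():
            assert (
                code_constraint(word, lexicon).value == "constrained"
            ) == constrained


class TestScheduling:
    def test_infeasible_config_reports_offenders(self):
        cfg = replace(
            SimConfig(),
            n_dyads=1,
            utterances_per_dyad=40,
            enforce_feasibility=False,
            dur_base_ms=250.0,
            dur_per_word_ms=80.0,  # turns far shorter than the 3-s lead
            fto_sd_ms=100.0,
            p_within=0.0,
            p_restart=0.0,
        )
        with pytest.raises(FeasibilityError) as exc:
            generate_conversation(cfg, 1, speakers=("A", "B"))
        assert len(exc.value.offenders) > 0

    def test_planted_type_matches_classifier(self):
        corpus = generate_corpus(SimConfig(), 17)
        for conv in corpus.dyads:
            typed = classify_utterances(conv.records)
            planted = [
                conv.truth["utterances"][f"{conv.dyad_id}:{k}"]["planted_type"]
                for k in range(len(conv.records))
            ]
            got = [t.utterance_type for t in typed]
            assert got == planted

    def test_proportions_recovered_within_binomial_band(self):
        cfg = SimConfig.from_proportions(
            0.5, 0.2, 0.3, n_dyads=10, utterances_per_dyad=60, posture_depth=0.0
        )
        corpus = generate_corpus(cfg, 7)
        typed = []
        for conv in corpus.dyads:
            typed += classify_utterances(conv.records)
        props = response_type_proportions(typed)
        n = sum(t.is_retained for t in typed)
        assert n >= 350
        for key, p in cfg.planted_proportions.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(props[key] - p) < 1.96 * se + 1e-12

    def test_fto_mean_recovered_under_clt_band(self):
        # long utterances keep the drawn offsets clear of physical clamps
        # (a speaker cannot respond before finishing their own turn)
        cfg = replace(
            SimConfig(),
            p_within=0.0,
            p_restart=0.0,
            posture_depth=0.0,
            wc_lognorm_mu=1.6,
            n_dyads=6,
            utterances_per_dyad=55,
        )
        corpus = generate_corpus(cfg, 11)
        typed = []
        for conv in corpus.dyads:
            typed += classify_utterances(conv.records)
        mean, sd, _ = fto_summary(typed)
        n = sum(t.utterance_type in ("gap", "between_overlap") for t in typed)
        assert n >= 250
        assert abs(mean - cfg.fto_mean_ms) < 3 * cfg.fto_sd_ms / np.sqrt(n)

    def test_restart_rate_near_config(self):
        cfg = replace(SimConfig(), p_within=0.0)
        corpus = generate_corpus(cfg, 19)
        typed = []
        for conv in corpus.dyads:
            typed += classify_utterances(conv.records)
        rate = np.mean([t.utterance_type == "restart" for t in typed])
        lo, hi = stats.binom.interval(0.999, len(typed), cfg.p_restart)
        assert lo / len(typed) <= rate <= 1.5 * hi / len(typed)


class TestConfig:
    def test_from_proportions_round_trip(self):
        cfg = SimConfig.from_proportions(0.47, 0.23, 0.30)
        got = cfg.planted_proportions
        assert got["gap"] == pytest.approx(0.47, abs=1e-9)
        assert got["between_overlap"] == pytest.approx(0.23, abs=1e-9)
        assert got["within_overlap"] == pytest.approx(0.30, abs=1e-9)

    def test_null_config_removes_all_constraint_signal(self):
        cfg = null_config()
        assert cfg.posture_depth == 0.0
        assert cfg.word_intercept_sd == 0.0
        surf = planted_effect_surface(cfg)
        assert (surf.effect == 0).all()

    def test_lead_respects_floor_and_cap(self):
        cfg = SimConfig()
        assert cfg.lead_ms(1) == cfg.max_lead_ms
        assert cfg.lead_ms(40) == cfg.min_lead_ms
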