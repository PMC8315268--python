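"""Slice models: backward selection, Johnson-Neyman, bootstrap bands."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prespeech.errors import DesignError
from prespeech.slices import (
    backward_select_random,
    bootstrap_predictions,
    fit_lmm,
    fit_speed_model,
    johnson_neyman,
    maximal_structure,
    slice_dataset,
)

WORDS_C = ["right", "no", "so", "well", "what"]
WORDS_U = ["yeah", "yes", "I", "it", "next"]


def make_dataset(
    rng,
    n=400,
    n_speakers=8,
    tau_int=15.0,
    tau_slope=10.0,
    tau_word=8.0,
    sigma=12.0,
    beta=(300.0, 20.0, 5.0, -25.0),
    response="area",
):
    """Direct simulation at the slice-table level (no conversations)."""
    sp = rng.integers(0, n_speakers, n)
    wc = 1 + rng.poisson(2.5, n)
    constrained = rng.random(n) < 0.4
    words = np.where(
        constrained,
        rng.choice(WORDS_C, n),
        rng.choice(WORDS_U, n),
    )
    lw = np.log10(wc)
    dummy = (~constrained).astype(float)
    u = rng.normal(0, tau_int, n_speakers)
    s = rng.normal(0, tau_slope, n_speakers)
    w_eff = {w: rng.normal(0, tau_word) for w in WORDS_C + WORDS_U}
    y = (
        beta[0]
        + beta[1] * dummy
        + beta[2] * lw
        + beta[3] * dummy * lw
        + u[sp]
        + s[sp] * lw
        + np.array([w_eff[w] for w in words])
        + rng.normal(0, sigma, n)
    )
    return pd.DataFrame(
        {
            "utterance_id": [f"u{i}" for i in range(n)],
            "speaker_id": [f"P{i}" for i in sp],
            "first_word": words,
            "word_count": wc,
            "constraint": np.where(constrained, "constrained", "unconstrained"),
            response: y,
        }
    )


class TestBackwardSelection:
    def test_planted_speaker_slopes_keep_the_maximal_structure(self):
        kept = 0
        for seed in range(15):
            rng = np.random.default_rng(100 + seed)
            df = make_dataset(rng, tau_slope=25.0, tau_word=10.0)
            res = backward_select_random(df)
            kept += res.random_structure == (
                "(1 + log10_word_count | speaker_id) + (1 | first_word)"
            )
        assert kept >= 8  # majority of seeds retain the maximal structure

    def test_no_cluster_variance_descends_to_small_structure(self):
        rng = np.random.default_rng(2)
        df = make_dataset(rng, tau_int=0.0, tau_slope=0.0, tau_word=0.0)
        res = backward_select_random(df)
        # every random term is unsupported: selection must have pruned
        assert "1 + log10_word_count | speaker_id" not in res.random_structure

    def test_single_cluster_factor_dropped_immediately(self):
        rng = np.random.default_rng(3)
        df = make_dataset(rng, n_speakers=1, tau_int=0.0, tau_slope=0.0)
        res = fit_lmm(df, maximal_structure())
        assert "speaker_id" not in res.random_structure

    def test_both_constraint_levels_required(self):
        rng = np.random.default_rng(4)
        df = make_dataset(rng)
        df["constraint"] = "constrained"
        with pytest.raises(DesignError):
            fit_lmm(df, ())


class TestJohnsonNeyman:
    def test_no_interaction_and_reliable_constraint_covers_whole_span(self):
        rng = np.random.default_rng(5)
        df = make_dataset(rng, beta=(300.0, 40.0, 0.0, 0.0), sigma=8.0)
        res = backward_select_random(df)
        jn = johnson_neyman(res, (0.0, 1.0))
        assert len(jn.moderator_bounds_log10) == 1
        lo, hi = jn.moderator_bounds_log10[0]
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(1.0, abs=1e-6)

    def test_null_model_gives_empty_region(self):
        rng = np.random.default_rng(6)
        df = make_dataset(rng, beta=(300.0, 0.0, 0.0, 0.0))
        res = backward_select_random(df)
        jn = johnson_neyman(res, (0.0, 1.0))
        assert jn.empty

    @pytest.mark.parametrize("df_mode", ["pointwise", "fixed"])
    def test_boundaries_match_grid_search_oracle(self, df_mode):
        rng = np.random.default_rng(7)
        df = make_dataset(rng)
        res = backward_select_random(df)
        span = (0.0, 1.2)
        jn = johnson_neyman(res, span, df_mode=df_mode)
        assert not jn.empty
        fit = res.fit
        ws = np.linspace(*span, 10_000)
        sig = np.zeros(ws.size, bool)
        mid_c = np.zeros(4)
        mid_c[1], mid_c[3] = 1.0, 0.5 * sum(span)
        for i, w in enumerate(ws):
            c = np.zeros(4)
            c[1], c[3] = 1.0, w
            s = c @ fit.beta
            se = np.sqrt(c @ fit.cov_beta @ c)
            d = (
                fit.satterthwaite_df(c)
                if df_mode == "pointwise"
                else fit.satterthwaite_df(mid_c)
            )
            sig[i] = s - stats.t.ppf(0.975, d) * se > 0
        idx = np.flatnonzero(sig)
        lo, hi = jn.moderator_bounds_log10[0]
        assert abs(ws[idx[0]] - lo) < 1e-3
        assert abs(ws[idx[-1]] - hi) < 1e-3

    def test_word_count_bounds_clipped_to_observed_span(self):
        rng = np.random.default_rng(8)
        df = make_dataset(rng, beta=(300.0, 40.0, 0.0, 0.0), sigma=8.0)
        res = backward_select_random(df)
        span = (0.0, 0.9)
        jn = johnson_neyman(res, span)
        for lo, hi in jn.word_count_bounds:
            assert 10 ** span[0] - 1e-9 <= lo <= hi <= 10 ** span[1] + 1e-9


class TestBootstrap:
    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        df = make_dataset(rng, n=150)
        res = backward_select_random(df)
        a = bootstrap_predictions(res, B=20, seed=5)
        b = bootstrap_predictions(res, B=20, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_near_zero_noise_shrinks_intervals(self):
        rng = np.random.default_rng(10)
        df = make_dataset(
            rng, n=200, tau_int=0, tau_slope=0, tau_word=0, sigma=1e-6
        )
        res = fit_lmm(df, ())  # boundary case: no noise left to estimate
        out = bootstrap_predictions(res, B=40, seed=1)
        widths = out["ci_high"] - out["ci_low"]
        assert (widths < 1e-3).all()  # vanishing against areas of ~300

    def test_coverage_of_planted_predictions(self):
        """Planted population prediction falls inside the 95% band at
        roughly the nominal rate (binomial tolerance)."""
        beta = np.array([300.0, 20.0, 5.0, -25.0])
        grid_wc, grid_dummy = 2, 1.0
        truth = beta[0] + beta[1] * grid_dummy + beta[2] * np.log10(grid_wc) \
            + beta[3] * grid_dummy * np.log10(grid_wc)
        hits = 0
        reps = 120
        for seed in range(reps):
            rng = np.random.default_rng(20_000 + seed)
            df = make_dataset(
                rng, n=150, tau_int=0, tau_slope=0, tau_word=0, sigma=12.0,
                beta=tuple(beta),
            )
            res = fit_lmm(df, ())
            out = bootstrap_predictions(res, word_counts=(2,), B=120, seed=seed)
            row = out[(out.word_count == 2) & (out.constraint == "unconstrained")]
            hits += bool(row.ci_low.iloc[0] <= truth <= row.ci_high.iloc[0])
        lo, hi = stats.binom.interval(0.999, reps, 0.95)
        assert lo <= hits <= hi


class TestSpeedModel:
    def test_positive_word_count_slope_recovered(self):
        rng = np.random.default_rng(11)
        df = make_dataset(
            rng, beta=(300.0, 0.0, 120.0, 0.0), sigma=40.0, response="max_speed"
        )
        res = fit_speed_model(df)
        term = res.terms["log10_word_count"]
        assert term["beta"] > 0
        assert term["p"] < 0.05

    def test_near_constant_speeds_give_null_slopes(self):
        rng = np.random.default_rng(12)
        df = make_dataset(
            rng,
            beta=(100.0, 0.0, 0.0, 0.0),
            tau_int=0.0, tau_slope=0.0, tau_word=0.0,
            sigma=1e-4,
            response="max_speed",
        )
        res = fit_speed_model(df)
        assert abs(res.terms["log10_word_count"]["beta"]) < 1e-4


def test_slice_dataset_selects_single_frame():
    from prespeech.core import AreaTrajectory
    from prespeech.io import epochs_to_table

    areas = np.arange(90.0)
    meta = {
        "speaker_id": "P1",
        "word_count": 2,
        "first_word": "so",
        "constraint": "constrained",
        "utterance_type": "gap",
    }
    table = epochs_to_table([AreaTrajectory("u", areas, np.zeros(90, bool))], [meta])
    for off, idx in [(-3000, 0), (-1500, 45), (0, 89)]:
        got = slice_dataset(table, off)
        assert len(got) == 1
        assert got["area"].iloc[0] == float(idx)
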