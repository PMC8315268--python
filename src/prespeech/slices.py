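"""Time-sliced moderated mixed models over lip-area epochs.

At each slice offset (default −3000 … 0 ms in 500-ms / 15-frame steps) a
linear mixed model is fitted to the lip area of every analysable utterance
at that single epoch frame::

    area ~ constraint * log10(word_count) + (random effects)

with the labial-constraint predictor dummy-coded 0 = constrained,
1 = unconstrained — so a *positive* constraint coefficient means larger
lip area for unconstrained utterances, the signature of an anticipatory
posture, and a *negative* interaction means the posture contrast shrinks
as utterances get longer. Word count is log10-transformed to correct its
extreme positive skew. Speaker and the utterance's first word are crossed
clustering factors.

The random-effects structure is chosen by deterministic backward
selection: start from the maximal structure (correlated intercept + log10
word-count slope by speaker, plus a first-word intercept) and simplify —
first drop intercept/slope correlations, then repeatedly drop the single
component (slope or intercept) with the smallest estimated variance
(ties: slopes before intercepts, then fewer levels) — until the first fit
that converges without a singularity warning; if even the intercept-only
structures fail, the model falls back to fixed effects only with a loud
diagnostic.

Johnson-Neyman regions report the moderator (log10 word-count) ranges over
which the constraint simple slope ``s(w) = b_constraint + b_interaction w``
is significantly *positive*, solving ``s(w)^2 = t_crit(df(w))^2 Var s(w)``
with Satterthwaite df recomputed at each boundary candidate (a fixed df is
available as an option), then clipping to the observed word-count span.

Prediction bands (for constrained/unconstrained utterances of 2 and 8
words) come from a parametric bootstrap: resimulate the response from the
fitted model, refit with the same random structure, and take percentile
intervals of the population-level predictions. No multiple-testing
correction is applied across slices; see the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from prespeech.core import slice_frame_index
from prespeech.errors import BootstrapError, DesignError
from prespeech.lmm import (
    CorrPair,
    LMMFit,
    VarComp,
    fit_mixed,
    intercept_design,
    pair_design,
    slope_design,
)

#: Default slice offsets (ms before acoustic onset).
SLICE_OFFSETS = (-3000, -2500, -2000, -1500, -1000, -500, 0)

FIXED_TERMS = (
    "Intercept",
    "constraint",
    "log10_word_count",
    "constraint:log10_word_count",
)


# ---------------------------------------------------------------------------
# random-structure descriptors


@dataclass(frozen=True)
class RETerm:
    """One random-effects term: intercept and/or slope over a factor."""

    factor: str  # "speaker_id" | "first_word"
    intercept: bool = True
    slope: str | None = None  # name of the within-cluster covariate
    correlated: bool = True  # only meaningful when intercept and slope

    def describe(self) -> str:
        if self.intercept and self.slope and self.correlated:
            return f"(1 + {self.slope} | {self.factor})"
        if self.intercept and self.slope:
            return f"(1 | {self.factor}) + (0 + {self.slope} | {self.factor})"
        if self.slope:
            return f"(0 + {self.slope} | {self.factor})"
        return f"(1 | {self.factor})"


def maximal_structure(slope: str = "log10_word_count") -> tuple[RETerm, ...]:
    """Maximal structure: correlated speaker intercept+slope, word intercept."""
    return (
        RETerm("speaker_id", intercept=True, slope=slope, correlated=True),
        RETerm("first_word", intercept=True),
    )


def describe_structure(structure: tuple[RETerm, ...]) -> str:
    return " + ".join(t.describe() for t in structure) if structure else "(none)"


# ---------------------------------------------------------------------------
# design construction


def fixed_design(df: pd.DataFrame, response: str = "area"):
    """Fixed-effects matrix, response vector, and covariate columns."""
    dummy = (df["constraint"].to_numpy() == "unconstrained").astype(float)
    lw = np.log10(df["word_count"].to_numpy(float))
    X = np.column_stack([np.ones(len(df)), dummy, lw, dummy * lw])
    return X, df[response].to_numpy(float), {"log10_word_count": lw}


def random_terms(df: pd.DataFrame, structure: tuple[RETerm, ...], covariates: dict):
    """Materialize RETerm descriptors into engine VarComp/CorrPair blocks."""
    terms = []
    for t in structure:
        codes, levels = pd.factorize(df[t.factor], sort=True)
        k = len(levels)
        if k < 2:
            continue  # inestimable with a single cluster
        x = covariates[t.slope] if t.slope else None
        if t.intercept and t.slope and t.correlated:
            terms.append(CorrPair(t.factor, pair_design(codes, k, x)))
        else:
            if t.intercept:
                terms.append(VarComp(t.factor, intercept_design(codes, k)))
            if t.slope:
                terms.append(
                    VarComp(f"{t.factor}:{t.slope}", slope_design(codes, k, x))
                )
    return terms


# ---------------------------------------------------------------------------
# fitting


@dataclass
class SliceModelResult:
    """One slice's fitted model: per-term estimates, df, and JN region."""

    offset_ms: int
    fit: LMMFit
    structure: tuple[RETerm, ...]
    random_structure: str
    n: int
    jn: "JNRegion | None" = None
    fallback_fixed_only: bool = False

    @property
    def terms(self) -> dict[str, dict[str, float]]:
        out = {}
        for j, name in enumerate(self.fit.names):
            out[name] = {
                "beta": float(self.fit.beta[j]),
                "se": float(self.fit.se[j]),
                "df": float(self.fit.df[j]),
                "t": float(self.fit.t_stats[j]),
                "p": float(self.fit.p_values[j]),
            }
        return out

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def singular(self) -> bool:
        return self.fit.singular


def fit_lmm(
    df: pd.DataFrame,
    structure: tuple[RETerm, ...],
    response: str = "area",
    offset_ms: int = 0,
) -> SliceModelResult:
    """Fit one slice model with a fixed random structure."""
    if df["constraint"].nunique() < 2:
        raise DesignError("both constraint levels must be present")
    X, y, cov = fixed_design(df, response)
    # factors with a single observed cluster are inestimable: drop at once
    estimable = tuple(t for t in structure if df[t.factor].nunique() >= 2)
    terms = random_terms(df, estimable, cov)
    fit = fit_mixed(X, y, terms, list(FIXED_TERMS))
    return SliceModelResult(
        offset_ms=offset_ms,
        fit=fit,
        structure=estimable,
        random_structure=describe_structure(estimable),
        n=len(df),
    )


def _simplify(
    structure: tuple[RETerm, ...],
    last_fit: LMMFit | None,
    level_counts: dict[str, int],
) -> tuple[RETerm, ...] | None:
    """One deterministic backward-selection step; None when exhausted."""
    structure = tuple(structure)
    # (1) drop intercept/slope correlations
    if any(t.intercept and t.slope and t.correlated for t in structure):
        return tuple(
            replace(t, correlated=False) if (t.intercept and t.slope) else t
            for t in structure
        )
    # (2) drop the single component (slope or intercept) with the smallest
    # estimated variance — the offending near-zero component goes first, so
    # well-supported terms survive instead of being discarded by a fixed
    # kind-ordering (ties: slopes before intercepts, then fewer levels)
    components: list[tuple[float, int, int, RETerm, str]] = []
    vcs = last_fit.variance_components if last_fit is not None else {}
    for t in structure:
        if t.slope:
            v = vcs.get(
                f"var({t.factor}|slope)", vcs.get(f"var({t.factor}:{t.slope})", np.inf)
            )
            components.append((v, 0, level_counts.get(t.factor, 0), t, "slope"))
        if t.intercept:
            key = f"var({t.factor}|intercept)" if t.slope else f"var({t.factor})"
            v = vcs.get(key, vcs.get(f"var({t.factor})", np.inf))
            components.append((v, 1, level_counts.get(t.factor, 0), t, "intercept"))
    if not components:
        return None
    _, _, _, target, kind = min(components, key=lambda c: (c[0], c[1], c[2]))
    out: list[RETerm] = []
    for t in structure:
        if t is target:
            if kind == "slope" and t.intercept:
                out.append(replace(t, slope=None, correlated=True))
            elif kind == "intercept" and t.slope:
                out.append(replace(t, intercept=False, correlated=True))
            # else: the term is gone entirely
        else:
            out.append(t)
    return tuple(out)


def backward_select_random(
    df: pd.DataFrame,
    maximal: tuple[RETerm, ...] | None = None,
    response: str = "area",
    offset_ms: int = 0,
) -> SliceModelResult:
    """Backward-select the random structure, maximal first.

    Returns the first structure whose fit converges without singularity;
    falls back to a fixed-effects-only fit with a loud diagnostic when even
    the intercept-only structures fail.
    """
    structure = maximal if maximal is not None else maximal_structure()
    level_counts = {t.factor: int(df[t.factor].nunique()) for t in structure}
    last_fit = None
    while structure:
        result = fit_lmm(df, structure, response=response, offset_ms=offset_ms)
        if result.converged and not result.singular:
            return result
        last_fit = result.fit
        nxt = _simplify(structure, last_fit, level_counts)
        if nxt is None:
            break
        structure = nxt
    warnings.warn(
        f"slice {offset_ms} ms: no random structure converged non-singularly; "
        "falling back to fixed effects only",
        stacklevel=2,
    )
    result = fit_lmm(df, (), response=response, offset_ms=offset_ms)
    result.fallback_fixed_only = True
    result.random_structure = "(none: fixed-effects fallback)"
    return result


# ---------------------------------------------------------------------------
# Johnson-Neyman


@dataclass
class JNRegion:
    """Moderator ranges where the constraint simple slope is significantly
    positive, in log10 units and as word counts (clipped to the data)."""

    moderator_bounds_log10: list[tuple[float, float]]
    word_count_bounds: list[tuple[float, float]]
    alpha: float
    moderator_span: tuple[float, float]

    @property
    def empty(self) -> bool:
        return not self.moderator_bounds_log10


def johnson_neyman(
    result: SliceModelResult,
    moderator_span: tuple[float, float],
    alpha: float = 0.05,
    df_mode: str = "pointwise",
    grid: int = 512,
) -> JNRegion:
    """Johnson-Neyman region for the labial-constraint simple slope.

    ``moderator_span`` is the observed (min, max) of log10 word count.
    ``df_mode="pointwise"`` recomputes Satterthwaite df at every candidate
    moderator value; ``"fixed"`` uses the df at the span midpoint.
    """
    fit = result.fit
    j_c = fit.names.index("constraint")
    j_i = fit.names.index("constraint:log10_word_count")
    lo, hi = moderator_span
    if hi < lo:
        raise ValueError("empty moderator span")

    c0 = np.zeros(fit.p)
    c0[j_c] = 1.0
    c1 = np.zeros(fit.p)
    c1[j_i] = 1.0

    # c' C c and its df are quadratic/rational in w, so the whole path comes
    # from one set of perturbed covariances (see LMMFit.satterthwaite_df_path)
    cc, ci, ii = (
        float(c0 @ fit.cov_beta @ c0),
        float(c0 @ fit.cov_beta @ c1),
        float(c1 @ fit.cov_beta @ c1),
    )
    fixed_df = float(fit.satterthwaite_df_path(c0, c1, np.array([0.5 * (lo + hi)]))[0])

    def margin(w) -> float:
        """Positive inside the significant-positive-slope region."""
        w = float(w)
        s = fit.beta[j_c] + w * fit.beta[j_i]
        se = np.sqrt(cc + 2 * w * ci + w * w * ii)
        if df_mode == "pointwise":
            df = float(fit.satterthwaite_df_path(c0, c1, np.array([w]))[0])
        else:
            df = fixed_df
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(s - tcrit * se)

    if hi == lo:
        b = ((lo, hi),) if margin(lo) > 0 else ()
        return JNRegion(list(b), [ _to_wc(i, moderator_span) for i in b], alpha, moderator_span)

    ws = np.linspace(lo, hi, grid)
    s_path = fit.beta[j_c] + ws * fit.beta[j_i]
    se_path = np.sqrt(cc + 2 * ws * ci + ws**2 * ii)
    if df_mode == "pointwise":
        df_path = fit.satterthwaite_df_path(c0, c1, ws)
    else:
        df_path = np.full(ws.shape, fixed_df)
    vals = s_path - stats.t.ppf(1.0 - alpha / 2.0, df_path) * se_path
    intervals: list[tuple[float, float]] = []
    start = ws[0] if vals[0] > 0 else None
    from scipy.optimize import brentq

    for k in range(1, grid):
        if vals[k - 1] <= 0 < vals[k]:
            start = brentq(margin, ws[k - 1], ws[k], xtol=1e-9)
        elif vals[k - 1] > 0 >= vals[k]:
            end = brentq(margin, ws[k - 1], ws[k], xtol=1e-9)
            if start is not None:
                intervals.append((start, end))
            start = None
    if start is not None:
        intervals.append((start, ws[-1]))

    wc_bounds = [_to_wc(iv, moderator_span) for iv in intervals]
    return JNRegion(intervals, wc_bounds, alpha, moderator_span)


def _to_wc(interval, span):
    lo, hi = span
    a = min(max(interval[0], lo), hi)
    b = min(max(interval[1], lo), hi)
    return (10.0**a, 10.0**b)


# ---------------------------------------------------------------------------
# bootstrap prediction bands


def bootstrap_predictions(
    result: SliceModelResult,
    word_counts=(2, 8),
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
    max_failure_rate: float = 0.10,
) -> pd.DataFrame:
    """Parametric-bootstrap percentile intervals for predicted lip areas.

    Predictions are population-level (random effects at zero) on the grid
    word_counts x {constrained, unconstrained}.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    fit = result.fit
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = pd.DataFrame(
        [
            {"word_count": wc, "constraint": lab}
            for wc in word_counts
            for lab in ("constrained", "unconstrained")
        ]
    )
    dummy = (grid["constraint"] == "unconstrained").astype(float).to_numpy()
    lw = np.log10(grid["word_count"].to_numpy(float))
    Xg = np.column_stack([np.ones(len(grid)), dummy, lw, dummy * lw])

    preds = np.empty((B, len(grid)))
    failures = 0
    kept = 0
    for b in range(B):
        y_star = fit.simulate(rng)
        try:
            refit = fit.refit(y_star)
        except Exception:
            failures += 1
            continue
        if not refit.converged:
            failures += 1
            continue
        preds[kept] = Xg @ refit.beta
        kept += 1
    if failures > max_failure_rate * B:
        raise BootstrapError(
            f"{failures}/{B} bootstrap refits failed (> {max_failure_rate:.0%})"
        )
    tail = 0.5 * (1.0 - level)
    lo, hi = np.quantile(preds[:kept], [tail, 1.0 - tail], axis=0)
    out = grid.copy()
    out["predicted"] = Xg @ fit.beta
    out["ci_low"] = lo
    out["ci_high"] = hi
    return out


# ---------------------------------------------------------------------------
# slice tables and the speed model


def slice_dataset(
    epoch_table: pd.DataFrame, offset_ms: int, n_frames: int = 90, fps: float = 30.0
) -> pd.DataFrame:
    """Rows of the tidy epoch table at one slice offset, missing dropped."""
    idx = slice_frame_index(offset_ms, n_frames=n_frames, fps=fps)
    target = (idx - n_frames) * 1000.0 / fps
    sel = np.isclose(epoch_table["slice_offset_ms"].to_numpy(float), target)
    df = epoch_table.loc[sel]
    return df.loc[~df["missing"]].reset_index(drop=True)


def fit_all_slices(
    epoch_table: pd.DataFrame,
    offsets=SLICE_OFFSETS,
    maximal: tuple[RETerm, ...] | None = None,
    alpha: float = 0.05,
    jn_df_mode: str = "pointwise",
    n_frames: int = 90,
    fps: float = 30.0,
    jn: bool = True,
) -> list[SliceModelResult]:
    """Backward-select and fit the slice model at every offset, attaching a
    Johnson-Neyman region where the interaction is reliable (``jn=False``
    skips the follow-up, e.g. for large simulation studies)."""
    results = []
    for off in offsets:
        df = slice_dataset(epoch_table, off, n_frames=n_frames, fps=fps)
        res = backward_select_random(df, maximal=maximal, offset_ms=off)
        lw = np.log10(df["word_count"].to_numpy(float))
        if jn and res.terms["constraint:log10_word_count"]["p"] < alpha:
            res.jn = johnson_neyman(
                res, (float(lw.min()), float(lw.max())), alpha=alpha, df_mode=jn_df_mode
            )
        results.append(res)
    return results


def results_table(results: list[SliceModelResult]) -> pd.DataFrame:
    """Long-format per-slice results table (one row per model term)."""
    rows = []
    for r in results:
        jn_lo = jn_hi = np.nan
        if r.jn is not None and not r.jn.empty:
            jn_lo = r.jn.word_count_bounds[0][0]
            jn_hi = r.jn.word_count_bounds[-1][1]
        for name, t in r.terms.items():
            rows.append(
                {
                    "offset_ms": r.offset_ms,
                    "random_structure": r.random_structure,
                    "term": name,
                    "beta": t["beta"],
                    "se": t["se"],
                    "df": t["df"],
                    "t": t["t"],
                    "p": t["p"],
                    "n": r.n,
                    "converged": r.converged,
                    "singular": r.singular,
                    "jn_low_word_count": jn_lo,
                    "jn_high_word_count": jn_hi,
                }
            )
    return pd.DataFrame(rows)


def fit_speed_model(
    speed_table: pd.DataFrame, maximal: tuple[RETerm, ...] | None = None
) -> SliceModelResult:
    """Mixed model for maximum lip movement speed (same fixed design)."""
    return backward_select_random(
        speed_table, maximal=maximal, response="max_speed", offset_ms=0
    )
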