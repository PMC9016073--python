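"""Condition-wise coherence statistics.

For every signal type and frequency band, the band-median coherence
series of each dyad is averaged over the eyes-closed (EC) and
eye-contact (EO) segments, giving two values per dyad. Across dyads
these are analysed with:

* an aligned-rank-transform (ART) factorial ANOVA with factors
  condition (within-dyad) and familiarity group (between-dyad) plus
  their interaction, Benjamini-Hochberg FDR-corrected across the
  signal x band family per effect;
* a shuffled-pair control: the identical coherence chain run on random
  pairings of subjects from *different* dyads, compared with the true
  pairs by a two-sided Wilcoxon rank-sum test. Coupling that survives
  this comparison cannot be an artifact of the shared protocol
  structure, since surrogate pairs experienced the same conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preproc import AlignedSeries, PreprocessedDyad
from .registry import BANDS, CONDITIONS, FrequencyBand
from .wtc import BandCoherenceSeries, dyad_wtc_set

logger = logging.getLogger(__name__)

EFFECTS = ("condition", "group", "condition:group")


# ---------------------------------------------------------------------------
# condition averages


def condition_average(
    series: BandCoherenceSeries, segments: dict[str, tuple[float, float]]
) -> dict[str, float]:
    """Mean of unmasked coherence inside each condition segment.

    Returns NaN for a segment whose samples are all masked or absent.
    """
    out = {}
    for cond in CONDITIONS:
        a, b = segments[cond]
        sel = (series.time >= a) & (series.time < b)
        vals = series.values[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning(
                "segment %s fully masked for %s/%s",
                cond, series.signal_type, series.band.name,
            )
            out[cond] = float("nan")
        else:
            out[cond] = float(vals.mean())
    return out


def corpus_condition_records(
    corpora: list[PreprocessedDyad],
    bands: dict[str, FrequencyBand] | None = None,
    signal_types: tuple[str, ...] | None = None,
    wtc_sets: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Tidy table of condition-averaged coherence for every dyad.

    Columns: dyad_id, group, signal_type, band, condition, coherence.
    Pass precomputed ``wtc_sets`` (dyad_id -> dyad_wtc_set output) to
    avoid recomputing the coherence fields.
    """
    bands = BANDS if bands is None else bands
    rows = []
    for pre in corpora:
        if wtc_sets is not None and pre.dyad_id in wtc_sets:
            wtc_set = wtc_sets[pre.dyad_id]
        else:
            wtc_set = dyad_wtc_set(pre, bands=bands, signal_types=signal_types)
        for (st, band_name), series in wtc_set.items():
            avg = condition_average(series, pre.segments)
            for cond, val in avg.items():
                rows.append(
                    {
                        "dyad_id": pre.dyad_id,
                        "group": pre.familiarity,
                        "signal_type": st,
                        "band": band_name,
                        "condition": cond,
                        "coherence": val,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aligned rank transform ANOVA


def _twoway_f(
    y: np.ndarray, a: np.ndarray, b: np.ndarray, effect: str
) -> tuple[float, float]:
    """Type-II F test of one effect in a two-way layout with interaction.

    ``a`` (condition) and ``b`` (group) are integer-coded factors. Model
    comparison on least-squares fits: the full model contains A, B and
    A:B; the reduced model drops the tested effect (main effects are
    tested against the model without the interaction, following the
    type-II convention).
    """
    n = y.size

    def design(include: set[str]) -> np.ndarray:
        cols = [np.ones(n)]
        if "A" in include:
            cols.append((a == 1).astype(float))
        if "B" in include:
            cols.append((b == 1).astype(float))
        if "AB" in include:
            cols.append(((a == 1) & (b == 1)).astype(float))
        return np.column_stack(cols)

    def rss(X: np.ndarray) -> tuple[float, int]:
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        return float(((y - fitted) ** 2).sum()), rank

    full_terms = {"A", "B", "AB"}
    if effect == "condition":
        r_full, rank_f = rss(design({"A", "B"}))
        r_red, rank_r = rss(design({"B"}))
    elif effect == "group":
        r_full, rank_f = rss(design({"A", "B"}))
        r_red, rank_r = rss(design({"A"}))
    else:  # interaction
        r_full, rank_f = rss(design(full_terms))
        r_red, rank_r = rss(design({"A", "B"}))
    # error term always from the full interaction model
    r_err, rank_err = rss(design(full_terms))
    df1 = rank_f - rank_r
    df2 = n - rank_err
    if df1 <= 0 or df2 <= 0:
        return float("nan"), float("nan")
    num = (r_red - r_full) / df1
    den = r_err / df2
    if den <= 0:
        # all responses identical after alignment: no evidence of effect
        return 0.0, 1.0
    F = num / den
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p


@dataclass
class ARTEntry:
    """ART ANOVA result for one signal type x band."""

    signal_type: str
    band: str
    effect: str
    F: float
    p: float
    p_adj: float = float("nan")


def art_anova(
    df: pd.DataFrame, response: str = "coherence"
) -> dict[str, tuple[float, float]]:
    """Aligned-rank-transform two-way ANOVA (condition x group).

    ``df`` holds one signal x band: columns dyad_id, group, condition and
    the response, two rows (conditions) per dyad. For each effect the
    responses are aligned by stripping the estimated contributions of
    every *other* effect (cell-mean decomposition), ranked across the
    whole dataset with average ranks for ties, and submitted to a
    parametric factorial ANOVA; only the aligned-for effect's F is kept.

    Returns {effect: (F, p)} for condition, group and condition:group.
    """
    d = df.dropna(subset=[response])
    y = d[response].to_numpy(float)
    a = (d["condition"] == CONDITIONS[1]).to_numpy(int)
    b = (d["group"] == "familiar").to_numpy(int)
    if y.size < 4 or len(np.unique(a)) < 2:
        raise ValueError("need both conditions and >= 2 dyads")
    single_group = len(np.unique(b)) < 2

    grand = y.mean()
    cell = np.zeros_like(y)
    mu_a = np.zeros_like(y)
    mu_b = np.zeros_like(y)
    for av in (0, 1):
        mu_a[a == av] = y[a == av].mean()
        for bv in (0, 1):
            m = (a == av) & (b == bv)
            if m.any():
                cell[m] = y[m].mean()
    for bv in (0, 1):
        m = b == bv
        if m.any():
            mu_b[m] = y[m].mean()

    resid = y - cell
    aligned = {
        "condition": resid + mu_a - grand,
        "group": resid + mu_b - grand,
        "condition:group": resid + cell - mu_a - mu_b + grand,
    }
    out = {}
    for effect, vals in aligned.items():
        if single_group and effect != "condition":
            out[effect] = (float("nan"), float("nan"))
            continue
        ranks = stats.rankdata(vals)
        if np.ptp(ranks) == 0:
            out[effect] = (0.0, 1.0)
            continue
        if single_group:
            out[effect] = _twoway_f(ranks, a, np.zeros_like(b), "condition")
        else:
            out[effect] = _twoway_f(ranks, a, b, effect)
    return out


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p_values, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def art_anova_table(records: pd.DataFrame) -> pd.DataFrame:
    """ART ANOVA for every signal x band, FDR per effect family.

    The FDR family is all signal_type x band tests of one effect,
    mirroring one results table per effect.
    """
    rows = []
    for (st, band), grp in records.groupby(["signal_type", "band"], sort=False):
        try:
            res = art_anova(grp)
        except ValueError as exc:
            logger.warning("ART skipped for %s/%s: %s", st, band, exc)
            continue
        for effect, (F, p) in res.items():
            rows.append(
                {"signal_type": st, "band": band, "effect": effect, "F": F, "p": p}
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adj"] = np.nan
    for effect in table["effect"].unique():
        m = table["effect"] == effect
        table.loc[m, "p_adj"] = fdr_adjust(table.loc[m, "p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# shuffled-pair control


def _pseudo_dyad(
    pre_i: PreprocessedDyad, si: int, pre_j: PreprocessedDyad, sj: int, name: str
) -> PreprocessedDyad:
    """A surrogate 'dyad' pairing subjects from two different dyads."""
    return PreprocessedDyad(
        dyad_id=name,
        familiarity="surrogate",
        signals=(pre_i.signals[si], pre_j.signals[sj]),
        segments=pre_i.segments,
        quality=(pre_i.quality[si], pre_j.quality[sj]),
    )


def surrogate_pair_ensemble(
    corpora: list[PreprocessedDyad],
    n_surrogates: int = 2400,
    seed: int | np.random.SeedSequence = 0,
    bands: dict[str, FrequencyBand] | None = None,
    signal_types: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Condition-averaged coherence for random cross-dyad pairings.

    Draws ``n_surrogates`` pairs with replacement, always combining two
    subjects from *different* dyads (true pairings and same-subject
    pairings can never occur), and runs the identical chain used for
    true pairs (:func:`corpus_condition_records` delegates to the same
    functions). Reproducible from ``seed``.
    """
    if len(corpora) < 2:
        raise ValueError("need >= 2 dyads to form surrogate pairs")
    rng = np.random.default_rng(seed)
    surrogates = []
    for k in range(n_surrogates):
        i, j = rng.choice(len(corpora), size=2, replace=False)
        si, sj = rng.integers(0, 2, size=2)
        surrogates.append(
            _pseudo_dyad(corpora[i], int(si), corpora[j], int(sj), f"surr{k:04d}")
        )
    return corpus_condition_records(surrogates, bands=bands, signal_types=signal_types)


def compare_true_vs_surrogate(
    true_values: np.ndarray, surrogate_values: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both samples have n <= 10 and no ties span
    the groups; tie-corrected normal approximation otherwise. Fully tied
    data yields p = 1.
    """
    x = np.asarray(true_values, float)
    x = x[np.isfinite(x)]
    y = np.asarray(surrogate_values, float)
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(x.size * y.size / 2.0), 1.0
    method = "exact" if (x.size <= 10 and y.size <= 10) else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def surrogate_comparison_table(
    true_records: pd.DataFrame, surrogate_records: pd.DataFrame
) -> pd.DataFrame:
    """Per signal/band/condition: true vs surrogate coherence rank-sum.

    FDR across all cells of one condition (one results table each).
    """
    rows = []
    keys = ["signal_type", "band", "condition"]
    surr_groups = dict(tuple(surrogate_records.groupby(keys)))
    for key, grp in true_records.groupby(keys):
        surr = surr_groups.get(key)
        if surr is None:
            continue
        tv = grp["coherence"].to_numpy()
        sv = surr["coherence"].to_numpy()
        tv, sv = tv[np.isfinite(tv)], sv[np.isfinite(sv)]
        if tv.size == 0 or sv.size == 0:
            continue
        U, p = compare_true_vs_surrogate(tv, sv)
        rows.append(
            dict(
                zip(keys, key),
                median_true=float(np.median(tv)),
                median_surrogate=float(np.median(sv)),
                U=U,
                p=p,
            )
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adj"] = np.nan
    for cond in table["condition"].unique():
        m = table["condition"] == cond
        table.loc[m, "p_adj"] = fdr_adjust(table.loc[m, "p"].to_numpy())
    return table
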