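"""Correlated-coherence analysis.

Beyond asking *whether* two people's signals cohere, this stage asks how
the strengths of different couplings co-vary over time: per dyad, band
and condition, the Spearman correlation between every pair of
band-median coherence series is assembled into a symmetric matrix
(29 x 29 for VLF/LF1/LF2, 28 x 28 for the cardiac band, which lacks
PETCO2). Group summaries keep only coefficients individually
significant at p < 0.05 and take the cell-wise median across dyads;
distributions of coefficients are compared between conditions — and,
for the eye-contact-minus-eyes-closed difference, between familiar and
unfamiliar dyads — with two-sample Kolmogorov-Smirnov tests,
Benjamini-Hochberg-corrected per band.

Series of different native rates are linearly interpolated onto a
common 4 Hz grid restricted to the condition segment; COI-masked
stretches stay missing and pairs are correlated over their pairwise-
complete samples. Because band-median coherence series are strongly
autocorrelated, nominal Spearman p-values are optimistic; an optional
decimation step (keep every k-th grid sample) is provided, with no
decimation as the default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coupling import fdr_adjust
from .registry import BAND_ORDER, CONDITIONS
from .wtc import BandCoherenceSeries

logger = logging.getLogger(__name__)

COMMON_GRID_HZ = 4.0
MIN_OVERLAP = 10


@dataclass
class WTCCorrelationMatrix:
    """Per-dyad Spearman matrix over one band's coherence series."""

    dyad_id: str
    band: str
    condition: str
    names: tuple[str, ...]
    r: np.ndarray  # (n, n), NaN where undefined
    p: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.r.shape != (n, n) or self.p.shape != (n, n):
            raise ValueError("matrix dimensions must match the name list")


@dataclass
class GroupMedianMatrix:
    """Cell-wise median of significant per-dyad coefficients."""

    band: str
    label: str  # condition or familiarity group
    names: tuple[str, ...]
    median: np.ndarray  # NaN where no dyad was significant
    support: np.ndarray  # number of contributing dyads per cell


def _to_common_grid(
    series: BandCoherenceSeries,
    interval: tuple[float, float],
    grid_hz: float = COMMON_GRID_HZ,
) -> np.ndarray:
    """Linear interpolation onto the segment's common grid.

    Grid points farther than two native sample periods from the nearest
    unmasked sample stay NaN, so COI gaps are not bridged.
    """
    a, b = interval
    grid = np.arange(a, b, 1.0 / grid_hz)
    ok = np.isfinite(series.values)
    if ok.sum() < 2:
        return np.full(grid.size, np.nan)
    t_ok = series.time[ok]
    v = np.interp(grid, t_ok, series.values[ok])
    # distance from each grid point to the nearest valid source sample
    idx = np.searchsorted(t_ok, grid).clip(1, t_ok.size - 1)
    dist = np.minimum(np.abs(grid - t_ok[idx - 1]), np.abs(grid - t_ok[idx]))
    v[dist > 2.0 / series.rate] = np.nan
    v[(grid < t_ok[0]) | (grid > t_ok[-1])] = np.nan
    return v


def spearman_wtc_matrix(
    series_by_signal: list[tuple[str, BandCoherenceSeries]],
    interval: tuple[float, float],
    dyad_id: str = "",
    band: str = "",
    condition: str = "",
    decimate: int = 1,
) -> WTCCorrelationMatrix:
    """Pairwise Spearman correlations among one band's coherence series.

    ``decimate`` > 1 keeps every k-th common-grid sample, a crude guard
    against autocorrelation-inflated significance (default: off).
    """
    if len(series_by_signal) < 2:
        raise ValueError("need >= 2 series for a correlation matrix")
    names = tuple(name for name, _ in series_by_signal)
    grids = [
        _to_common_grid(s, interval)[::decimate] for _, s in series_by_signal
    ]
    n = len(names)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(grids[i]) & np.isfinite(grids[j])
            if ok.sum() < MIN_OVERLAP:
                continue
            res = stats.spearmanr(grids[i][ok], grids[j][ok])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    return WTCCorrelationMatrix(dyad_id, band, condition, names, r, p)


def dyad_correlation_matrices(
    wtc_set: dict[tuple[str, str], BandCoherenceSeries],
    segments: dict[str, tuple[float, float]],
    dyad_id: str = "",
    bands: tuple[str, ...] = BAND_ORDER,
    decimate: int = 1,
) -> dict[tuple[str, str], WTCCorrelationMatrix]:
    """Spearman matrices for every band x condition of one dyad."""
    from .wtc import ordered_band_items

    out = {}
    for band in bands:
        items = ordered_band_items(wtc_set, band)
        if len(items) < 2:
            continue
        for cond in CONDITIONS:
            out[(band, cond)] = spearman_wtc_matrix(
                items, segments[cond], dyad_id, band, cond, decimate
            )
    return out


def group_median_significant(
    matrices: list[WTCCorrelationMatrix], alpha: float = 0.05, label: str = ""
) -> GroupMedianMatrix:
    """Cell-wise median over dyads of individually significant r values."""
    if not matrices:
        raise ValueError("need >= 1 matrix")
    names = matrices[0].names
    for m in matrices:
        if m.names != names:
            raise ValueError("matrices must share the signal ordering")
    stack_r = np.array([m.r for m in matrices])
    stack_p = np.array([m.p for m in matrices])
    sig = np.isfinite(stack_r) & (stack_p < alpha)
    masked = np.where(sig, stack_r, np.nan)
    support = sig.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(masked, axis=0)
    band = matrices[0].band
    return GroupMedianMatrix(band, label, names, median, support)


def _cell_distributions(
    matrices: list[WTCCorrelationMatrix], values: list[np.ndarray] | None = None
) -> tuple[tuple[str, ...], np.ndarray]:
    names = matrices[0].names
    stack = np.array([m.r for m in matrices]) if values is None else np.array(values)
    return names, stack


def ks_condition_compare(
    matrices_ec: list[WTCCorrelationMatrix],
    matrices_eo: list[WTCCorrelationMatrix],
) -> pd.DataFrame:
    """Cell-wise two-sample KS test of EC vs EO coefficient distributions.

    Returns a tidy table (band, row, col, D, p, p_adj, direction) over
    the upper triangle; the diagonal never enters. FDR within the band.
    """
    names, stack_ec = _cell_distributions(matrices_ec)
    names_eo, stack_eo = _cell_distributions(matrices_eo)
    if names != names_eo:
        raise ValueError("condition matrices must share the signal ordering")
    band = matrices_ec[0].band
    rows = []
    n = len(names)
    for i in range(n):
        for j in range(i + 1, n):
            a = stack_ec[:, i, j]
            b = stack_eo[:, i, j]
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if a.size == 0 or b.size == 0:
                continue
            res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
            direction = CONDITIONS[1] if np.median(b) > np.median(a) else CONDITIONS[0]
            rows.append(
                {
                    "band": band,
                    "row": names[i],
                    "col": names[j],
                    "D": float(res.statistic),
                    "p": float(res.pvalue),
                    "direction": direction,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = fdr_adjust(table["p"].to_numpy())
    return table


def familiarity_contrast(
    matrices_by_dyad: dict[str, dict[str, WTCCorrelationMatrix]],
    familiarity: dict[str, str],
) -> tuple[dict[str, GroupMedianMatrix], pd.DataFrame]:
    """Familiar vs unfamiliar contrast on condition-difference matrices.

    Per dyad, Delta = r(eye contact) - r(eyes closed) cell-wise; the two
    familiarity groups are summarised by their cell-wise median Delta
    (all finite values; significance filtering does not apply to
    differences) and compared per cell with a two-sample KS test, FDR
    within the band.
    """
    deltas: dict[str, list[np.ndarray]] = {"familiar": [], "unfamiliar": []}
    names = None
    band = None
    for dyad_id, conds in matrices_by_dyad.items():
        group = familiarity[dyad_id]
        m_ec = conds[CONDITIONS[0]]
        m_eo = conds[CONDITIONS[1]]
        if names is None:
            names, band = m_ec.names, m_ec.band
        deltas[group].append(m_eo.r - m_ec.r)
    if not deltas["familiar"] or not deltas["unfamiliar"]:
        raise ValueError("both familiarity groups must be nonempty")

    medians = {}
    for group, stack in deltas.items():
        arr = np.array(stack)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(arr, axis=0)
        support = np.isfinite(arr).sum(axis=0)
        medians[group] = GroupMedianMatrix(band, group, names, med, support)

    rows = []
    fam = np.array(deltas["familiar"])
    unf = np.array(deltas["unfamiliar"])
    n = len(names)
    for i in range(n):
        for j in range(i + 1, n):
            a = fam[:, i, j]
            b = unf[:, i, j]
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if a.size == 0 or b.size == 0:
                continue
            res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
            direction = "familiar" if np.median(a) > np.median(b) else "unfamiliar"
            rows.append(
                {
                    "band": band,
                    "row": names[i],
                    "col": names[j],
                    "D": float(res.statistic),
                    "p": float(res.pvalue),
                    "direction": direction,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = fdr_adjust(table["p"].to_numpy())
    return medians, table
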