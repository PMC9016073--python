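"""fNIRS preprocessing and session alignment.

The processing chain mirrors the standard continuous-wave pipeline:

1. raw intensity -> optical density (OD), referenced to the temporal mean;
2. channel quality control by coefficient of variation (CV) of the raw
   intensity, excluding channels with CV above 7.5% at either wavelength;
3. short-separation regression (SSR) on OD, per wavelength: each long
   channel has the least-squares-scaled signal of its nearest short
   channel subtracted, removing superficial (scalp) hemodynamics;
4. modified Beer-Lambert law (MBLL) conversion of the two-wavelength OD
   into chromophore concentration changes d[O2Hb], d[HHb] (micromolar),
   with d[tHb] their sum, using a fixed differential pathlength factor
   (DPF) of 6;
5. averaging of included channels into three regions of interest (left,
   right, left+right), in both SSR-corrected and uncorrected ("raw")
   variants -> 18 fNIRS signal types;
6. synchronisation with the systemic series on the shared session clock
   and removal of the discarded 1-minute prebaseline.

CV is evaluated on raw intensity (sample standard deviation, n-1
denominator), before OD conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .registry import (
    DEFAULT_DPF,
    FNIRS_SIGNALS,
    Montage,
    SYSTEMIC_SIGNALS,
    extinction_matrix,
    fnirs_signal_name,
)
from .synthetic import DyadSession

logger = logging.getLogger(__name__)

CV_THRESHOLD_PERCENT = 7.5


@dataclass(frozen=True)
class MBLLParams:
    """Constants of the modified Beer-Lambert conversion."""

    ext_matrix: np.ndarray = field(default_factory=extinction_matrix)
    dpf: float = DEFAULT_DPF
    distance_cm: float = 3.0

    def __post_init__(self) -> None:
        E = np.asarray(self.ext_matrix, float)
        if E.shape != (2, 2) or abs(np.linalg.det(E)) < 1e-12:
            raise ValueError("extinction matrix must be 2x2 and invertible")
        if self.dpf <= 0 or self.distance_cm <= 0:
            raise ValueError("DPF and distance must be > 0")


@dataclass
class ChannelQuality:
    """QC verdict for one long channel (worst wavelength decides)."""

    channel: int
    cv_percent: tuple[float, ...]  # per wavelength
    included: bool
    reason: str = ""


@dataclass
class AlignedSeries:
    """One named series on the session clock."""

    time: np.ndarray
    values: np.ndarray
    rate: float


@dataclass
class PreprocessedDyad:
    """Both subjects' 29 aligned signal types plus segment intervals."""

    dyad_id: str
    familiarity: str
    signals: tuple[dict[str, AlignedSeries], dict[str, AlignedSeries]]
    segments: dict[str, tuple[float, float]]
    quality: tuple[list[ChannelQuality], list[ChannelQuality]]


# ---------------------------------------------------------------------------
# elementary operations


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """OD(t) = -ln(I(t) / mean_t I); zero-mean-ish by construction."""
    I = np.asarray(intensity, float)
    if np.any(I <= 0):
        raise ValueError("nonpositive intensity sample; channel invalid")
    return -np.log(I / I.mean())


def channel_quality_cv(
    intensity: np.ndarray, threshold_percent: float = CV_THRESHOLD_PERCENT
) -> tuple[float, bool]:
    """Coefficient of variation (%) and inclusion verdict.

    CV = 100 * sd / mean with the sample (n-1) standard deviation;
    a channel is excluded only when CV is strictly above the threshold.
    """
    I = np.asarray(intensity, float)
    if I.size < 2:
        raise ValueError("need at least 2 samples for a CV")
    mean = I.mean()
    if mean <= 0:
        return float("inf"), False
    cv = 100.0 * I.std(ddof=1) / mean
    return cv, cv <= threshold_percent


def short_separation_regress(
    long_od: np.ndarray, short_od: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares scaled subtraction of the short channel.

    corrected = long - alpha * short with
    alpha = <long, short> / <short, short> on mean-centred series, so
    the corrected series is orthogonal to the short-channel signal.
    Returns (corrected, alpha); a zero-variance short channel leaves the
    long channel unchanged (alpha = 0) with a warning.
    """
    lo = np.asarray(long_od, float)
    sh = np.asarray(short_od, float)
    if lo.shape != sh.shape:
        raise ValueError("long and short series must have equal length")
    lc = lo - lo.mean()
    sc = sh - sh.mean()
    denom = float(sc @ sc)
    if denom == 0.0:
        logger.warning("short channel has zero variance; SSR skipped")
        return lo.copy(), 0.0
    alpha = float(lc @ sc) / denom
    return lo - alpha * sc, alpha


def od_to_concentration(
    od: np.ndarray, params: MBLLParams | None = None
) -> np.ndarray:
    """Chromophore changes from two-wavelength OD.

    ``od`` has shape (2, n_samples) ordered as the extinction-matrix rows.
    Returns (n_samples, 3): d[O2Hb], d[HHb], d[tHb] in micromolar.
    """
    params = MBLLParams() if params is None else params
    od = np.asarray(od, float)
    if od.ndim != 2 or od.shape[0] != 2:
        raise ValueError("od must have shape (2, n_samples)")
    A = np.asarray(params.ext_matrix, float) * params.distance_cm * params.dpf
    conc_mM = np.linalg.solve(A, od)  # (2, n_samples)
    conc_um = conc_mM.T * 1e3
    return np.column_stack([conc_um, conc_um.sum(axis=1)])


def average_rois(
    conc_by_channel: dict[int, np.ndarray],
    quality: list[ChannelQuality],
    montage: Montage,
    variant: str,
) -> dict[str, np.ndarray]:
    """Unweighted mean of included channels per ROI.

    ``conc_by_channel`` maps long-channel index -> (n_samples, 3) array.
    Emits 9 series ({O2Hb, HHb, tHb} x {left, right, both}) for the given
    variant; an ROI whose channels were all excluded is omitted (and
    logged), and downstream stages skip the missing series.
    """
    included = {q.channel for q in quality if q.included}
    out: dict[str, np.ndarray] = {}
    roi_members = {
        "left": [c.index for c in montage.roi_channels("left") if c.index in included],
        "right": [c.index for c in montage.roi_channels("right") if c.index in included],
    }
    roi_members["both"] = roi_members["left"] + roi_members["right"]
    for roi, members in roi_members.items():
        if not members:
            logger.warning("ROI %s has no included channels; series missing", roi)
            continue
        stacked = np.mean([conc_by_channel[i] for i in members], axis=0)
        for k, chromo in enumerate(("O2Hb", "HHb", "tHb")):
            out[fnirs_signal_name(chromo, roi, variant)] = stacked[:, k]
    return out


# ---------------------------------------------------------------------------
# per-subject chain


def preprocess_subject(
    fnirs_time: np.ndarray,
    intensity: np.ndarray,
    montage: Montage,
    params: MBLLParams | None = None,
    cv_threshold: float = CV_THRESHOLD_PERCENT,
) -> tuple[dict[str, np.ndarray], list[ChannelQuality]]:
    """Raw intensities -> the 18 fNIRS signal types of one subject."""
    params = MBLLParams() if params is None else params
    n_wl = intensity.shape[1]

    quality: list[ChannelQuality] = []
    for ch in montage.long_channels:
        cvs, ok = [], True
        reason = ""
        for wi in range(n_wl):
            try:
                cv, inc = channel_quality_cv(intensity[ch.index, wi], cv_threshold)
            except ValueError as exc:
                cv, inc = float("inf"), False
                reason = str(exc)
            cvs.append(cv)
            ok = ok and inc
        if not ok and not reason:
            reason = f"CV above {cv_threshold}%"
        quality.append(ChannelQuality(ch.index, tuple(cvs), ok, reason))

    # OD for every channel/wavelength; intensity rows follow the montage
    # channel order (long channels first, then short channels)
    od: dict[int, np.ndarray | None] = {}
    for row, ch in enumerate(montage.channels):
        try:
            od[row] = np.stack(
                [intensity_to_od(intensity[row, wi]) for wi in range(n_wl)]
            )
        except ValueError:
            if ch.kind == "long":
                for q in quality:
                    if q.channel == ch.index:
                        q.included = False
                        q.reason = "nonpositive intensity"
            od[row] = None

    n_long = len(montage.long_channels)
    conc_raw: dict[int, np.ndarray] = {}
    conc_corr: dict[int, np.ndarray] = {}
    for ch in montage.long_channels:
        if od[ch.index] is None:
            continue
        raw_od = od[ch.index]
        short_od = od[n_long + ch.paired_short]
        if short_od is None:
            corr_od = raw_od.copy()
        else:
            corr_od = np.stack(
                [
                    short_separation_regress(raw_od[wi], short_od[wi])[0]
                    for wi in range(n_wl)
                ]
            )
        mp = MBLLParams(params.ext_matrix, params.dpf, ch.distance_cm)
        conc_raw[ch.index] = od_to_concentration(raw_od, mp)
        conc_corr[ch.index] = od_to_concentration(corr_od, mp)

    signals = {}
    signals.update(average_rois(conc_corr, quality, montage, "corrected"))
    signals.update(average_rois(conc_raw, quality, montage, "raw"))
    return signals, quality


# ---------------------------------------------------------------------------
# session-level alignment


def synchronize_and_segment(session: DyadSession) -> PreprocessedDyad:
    """Full per-dyad preprocessing: both subjects' 29 aligned signals.

    Runs the fNIRS chain for each subject, attaches the systemic series,
    drops the prebaseline from every series and returns the two
    condition intervals on the shared session clock.
    """
    cfg = session.config
    protocol = cfg.protocol
    segs = protocol.segments()
    t0 = segs["prebaseline"][1]
    session_end = protocol.session_s

    all_signals: list[dict[str, AlignedSeries]] = []
    all_quality: list[list[ChannelQuality]] = []
    for subj in session.subjects:
        if subj.fnirs_time[-1] < session_end - 1.5 / cfg.fnirs_rate:
            raise ValueError(
                f"fNIRS series ends at {subj.fnirs_time[-1]:.1f} s, "
                f"short of the {session_end:.0f} s protocol"
            )
        fnirs, quality = preprocess_subject(
            subj.fnirs_time, subj.fnirs_intensity, cfg.montage
        )
        keep = subj.fnirs_time >= t0
        aligned: dict[str, AlignedSeries] = {
            name: AlignedSeries(subj.fnirs_time[keep], v[keep], cfg.fnirs_rate)
            for name, v in fnirs.items()
        }
        for st in SYSTEMIC_SIGNALS:
            if st not in subj.physio:
                logger.warning("systemic signal %s missing; skipped", st)
                continue
            t, v = subj.physio[st]
            rate = cfg.capno_rate if st == "PETCO2" else cfg.physio_rate
            if t[-1] < session_end - 1.5 / rate:
                raise ValueError(
                    f"systemic series {st} ends at {t[-1]:.1f} s, "
                    f"short of the {session_end:.0f} s protocol"
                )
            keep = t >= t0
            aligned[st] = AlignedSeries(t[keep], v[keep], rate)
        all_signals.append(aligned)
        all_quality.append(quality)

    return PreprocessedDyad(
        dyad_id=session.dyad_id,
        familiarity=session.familiarity,
        signals=(all_signals[0], all_signals[1]),
        segments={k: segs[k] for k in ("eyes_closed", "eye_contact")},
        quality=(all_quality[0], all_quality[1]),
    )
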