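"""Morlet wavelet-transform coherence (WTC) and band-median reduction.

The coherence of two series x(t), y(t) is computed on a dyadic grid of
wavelet scales as

    R^2(s, t) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

where W_x, W_y are continuous Morlet (omega0 = 6) wavelet transforms,
W_xy = W_x * conj(W_y), and S is a smoothing operator: a Gaussian in time
(std s / sqrt(2)) followed by a boxcar across scales spanning 0.6 of the
decorrelation length. Smoothing with a common positive kernel makes R^2
a Cauchy-Schwarz ratio, hence bounded in [0, 1], and exactly 1 for
self-coherence.

Scales follow the dyadic convention s_j = s0 * 2**(j*dj) with s0 = 2*dt
and dj = 1/12; the equivalent Fourier period is lambda = c * s with
c = 4*pi / (omega0 + sqrt(2 + omega0**2)) ~ 1.033. Edge effects are
handled by zero-padding to the next power of two and excluding the cone
of influence (COI): the e-folding time of the Morlet envelope is
sqrt(2)*s, so at distance d from the nearest edge only periods up to
c * d / sqrt(2) are trusted.

Coherence is computed over the full analysis span and segmented
afterwards, so scales down to the lowest band edge (0.002 Hz) remain
reachable; the COI accounts for the edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft as spfft
from scipy.ndimage import uniform_filter1d

from .preproc import PreprocessedDyad
from .registry import BAND_ORDER, BANDS, FrequencyBand

logger = logging.getLogger(__name__)

OMEGA0 = 6.0
#: Fourier period per unit scale for the omega0 = 6 Morlet wavelet.
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))
DEFAULT_DJ = 1.0 / 12.0


@dataclass
class WTCField:
    """Squared wavelet coherence on a (scale, time) grid with its COI."""

    rsq: np.ndarray  # (n_scales, n_times), NaN where undefined
    scales: np.ndarray  # seconds
    freqs: np.ndarray  # equivalent Fourier frequencies, Hz
    coi_period: np.ndarray  # (n_times,) max trusted Fourier period, s
    time: np.ndarray
    rate: float

    @property
    def valid(self) -> np.ndarray:
        """Boolean (n_scales, n_times): inside the cone of influence."""
        period = FOURIER_FACTOR * self.scales
        return period[:, None] <= self.coi_period[None, :]


@dataclass
class BandCoherenceSeries:
    """Median coherence over the scales of one band, versus time."""

    signal_type: str
    band: FrequencyBand
    time: np.ndarray
    values: np.ndarray  # NaN = fully COI-masked (or band unreachable)
    rate: float
    note: str = ""


# ---------------------------------------------------------------------------
# continuous wavelet transform


def _scale_grid(
    dt: float, n: int, dj: float = DEFAULT_DJ, max_period: float | None = None
) -> np.ndarray:
    """Dyadic scales from s0 = 2*dt up to ``max_period`` (default: the
    series duration), expressed in seconds."""
    s0 = 2.0 * dt
    if max_period is None:
        max_period = n * dt
    max_scale = max_period / FOURIER_FACTOR
    J = max(int(np.ceil(np.log2(max_scale / s0) / dj)), 1)
    return s0 * 2.0 ** (dj * np.arange(J + 1))


def morlet_cwt(
    x: np.ndarray,
    rate: float,
    scales: np.ndarray | None = None,
    dj: float = DEFAULT_DJ,
    max_period: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous Morlet (omega0 = 6) wavelet transform.

    Returns (W, scales, coi_period): W is complex (n_scales, n), and
    coi_period[t] is the largest trusted Fourier period at sample t.
    The input is demeaned and zero-padded to the next power of two.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 64:
        raise ValueError("series too short for a wavelet transform (< 64 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples")
    dt = 1.0 / rate
    if scales is None:
        scales = _scale_grid(dt, n, dj, max_period)
    n_pad = int(2 ** np.ceil(np.log2(n)))
    xpad = np.zeros(n_pad)
    xpad[:n] = x - x.mean()
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)
    xhat = spfft.fft(xpad)
    positive = omega > 0
    norm_const = np.pi**-0.25
    psi_hat = np.zeros((scales.size, n_pad))
    psi_hat[:, positive] = norm_const * np.sqrt(
        2.0 * np.pi * scales[:, None] / dt
    ) * np.exp(-0.5 * (scales[:, None] * omega[positive] - OMEGA0) ** 2)
    W = spfft.ifft(xhat[None, :] * psi_hat, axis=1)[:, :n]
    edge = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    coi_period = FOURIER_FACTOR / np.sqrt(2.0) * np.maximum(edge, dt * 1e-8)
    return W, scales, coi_period


# ---------------------------------------------------------------------------
# smoothing


def _smooth_time(field: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Per-scale Gaussian time smoothing with std s/sqrt(2), via FFT."""
    n = field.shape[1]
    n_pad = spfft.next_fast_len(n + n // 2)  # generous zero-pad against wrap-around
    sigma = scales[:, None] / np.sqrt(2.0)
    if np.iscomplexobj(field):
        omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)
        kernel_hat = np.exp(-0.5 * (sigma * omega[None, :]) ** 2)
        padded = np.zeros((field.shape[0], n_pad), complex)
        padded[:, :n] = field
        return spfft.ifft(spfft.fft(padded, axis=1) * kernel_hat, axis=1)[:, :n]
    omega = 2.0 * np.pi * np.fft.rfftfreq(n_pad, d=dt)
    kernel_hat = np.exp(-0.5 * (sigma * omega[None, :]) ** 2)
    padded = np.zeros((field.shape[0], n_pad))
    padded[:, :n] = field
    return spfft.irfft(spfft.rfft(padded, axis=1) * kernel_hat, n=n_pad, axis=1)[:, :n]


def _smooth_scale(field: np.ndarray, dj: float, width_dj: float = 0.6) -> np.ndarray:
    """Boxcar across scales spanning ``width_dj`` decorrelation lengths.

    Edge windows are renormalised by their actual overlap with the grid.
    """
    w = max(int(round(width_dj / dj)), 1)
    if w <= 1:
        return field.copy()

    def box(f: np.ndarray) -> np.ndarray:
        return uniform_filter1d(f, size=w, axis=0, mode="constant", cval=0.0)

    counts = uniform_filter1d(
        np.ones(field.shape[0]), size=w, mode="constant", cval=0.0
    )
    if np.iscomplexobj(field):
        sm = box(field.real) + 1j * box(field.imag)
    else:
        sm = box(field)
    return sm / counts[:, None]


def _smooth(field: np.ndarray, scales: np.ndarray, dt: float, dj: float) -> np.ndarray:
    return _smooth_scale(_smooth_time(field, scales, dt), dj)


# ---------------------------------------------------------------------------
# coherence


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    dj: float = DEFAULT_DJ,
    max_period: float | None = None,
    time: np.ndarray | None = None,
) -> WTCField:
    """Squared wavelet coherence of two equally sampled series."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    dt = 1.0 / rate
    n = x.size
    if time is None:
        time = np.arange(n) * dt
    if x.std() == 0 or y.std() == 0:
        logger.warning("constant input; coherence undefined")
        scales = _scale_grid(dt, n, dj, max_period)
        coi = FOURIER_FACTOR / np.sqrt(2.0) * np.minimum(
            np.arange(n), np.arange(n)[::-1]
        ) * dt
        nanfield = np.full((scales.size, n), np.nan)
        return WTCField(nanfield, scales, 1.0 / (FOURIER_FACTOR * scales), coi, time, rate)

    Wx, scales, coi_period = morlet_cwt(x, rate, dj=dj, max_period=max_period)
    Wy, _, _ = morlet_cwt(y, rate, scales=scales)
    inv_s = 1.0 / scales[:, None]
    Sxx = _smooth(np.abs(Wx) ** 2 * inv_s, scales, dt, dj)
    Syy = _smooth(np.abs(Wy) ** 2 * inv_s, scales, dt, dj)
    Sxy = _smooth(Wx * np.conj(Wy) * inv_s, scales, dt, dj)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsq = np.abs(Sxy) ** 2 / (Sxx * Syy)
    rsq = np.clip(rsq, 0.0, 1.0)
    freqs = 1.0 / (FOURIER_FACTOR * scales)
    return WTCField(rsq, scales, freqs, coi_period, np.asarray(time, float), rate)


def band_median_series(
    field: WTCField, band: FrequencyBand, signal_type: str = ""
) -> BandCoherenceSeries:
    """Per-time-point median of R^2 over the band's scales, COI-masked.

    Time points whose in-band scales are all outside the COI become NaN.
    A band lying entirely above the Nyquist frequency (or below the
    largest resolved period) yields an all-NaN series with a note rather
    than an error.
    """
    in_band = band.contains(field.freqs)
    n = field.time.size
    if not np.any(in_band):
        note = (
            f"band {band.name} ({band.f_low}-{band.f_high} Hz) outside the "
            f"resolved frequency range at rate {field.rate} Hz"
        )
        logger.warning(note)
        return BandCoherenceSeries(
            signal_type, band, field.time, np.full(n, np.nan), field.rate, note
        )
    sub = np.where(field.valid[in_band], field.rsq[in_band], np.nan)
    # columns that are fully COI-masked yield NaN by design
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(sub, axis=0)
    return BandCoherenceSeries(signal_type, band, field.time, med, field.rate)


# ---------------------------------------------------------------------------
# dyad-level driver


def signal_pair_band_series(
    xs: "np.ndarray",
    ys: "np.ndarray",
    rate: float,
    time: np.ndarray,
    signal_type: str,
    bands: dict[str, FrequencyBand] | None = None,
    dj: float = DEFAULT_DJ,
) -> dict[str, BandCoherenceSeries]:
    """WTC of one homologous signal pair reduced to band medians.

    Bands whose lower edge is at or above the Nyquist frequency are
    skipped entirely (this is what removes PETCO2 from the HR band).
    """
    bands = BANDS if bands is None else bands
    nyq = rate / 2.0
    reachable = {k: b for k, b in bands.items() if b.f_low < nyq}
    if not reachable:
        return {}
    lowest = min(b.f_low for b in reachable.values())
    max_period = min(1.0 / lowest, time.size / rate)
    field = wavelet_coherence(xs, ys, rate, dj=dj, max_period=max_period, time=time)
    return {
        k: band_median_series(field, b, signal_type) for k, b in reachable.items()
    }


def dyad_wtc_set(
    pre: PreprocessedDyad,
    bands: dict[str, FrequencyBand] | None = None,
    signal_types: tuple[str, ...] | None = None,
    dj: float = DEFAULT_DJ,
) -> dict[tuple[str, str], BandCoherenceSeries]:
    """All band-median coherence series of one dyad.

    Computes the WTC between each signal type of subject A and the same
    type of subject B, then reduces to the four band medians. With the
    full 29-signal registry this yields (29 x 4) - 1 = 115 series
    (PETCO2, sampled at 1 Hz, cannot reach the HR band).
    """
    bands = BANDS if bands is None else bands
    sig_a, sig_b = pre.signals
    if signal_types is None:
        signal_types = tuple(s for s in sig_a if s in sig_b)
    out: dict[tuple[str, str], BandCoherenceSeries] = {}
    for st in signal_types:
        if st not in sig_a or st not in sig_b:
            logger.warning("signal %s missing in one subject; skipped", st)
            continue
        a, b = sig_a[st], sig_b[st]
        n = min(a.values.size, b.values.size)
        series = signal_pair_band_series(
            a.values[:n], b.values[:n], a.rate, a.time[:n], st, bands, dj
        )
        for band_name, bcs in series.items():
            out[(st, band_name)] = bcs
    return out


def ordered_band_items(
    wtc_set: dict[tuple[str, str], BandCoherenceSeries], band_name: str
) -> list[tuple[str, BandCoherenceSeries]]:
    """Series of one band in stable registry order."""
    from .registry import SIGNAL_TYPES

    return [
        (st, wtc_set[(st, band_name)])
        for st in SIGNAL_TYPES
        if (st, band_name) in wtc_set
    ]
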