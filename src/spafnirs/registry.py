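"""Signal-type registry, frequency bands, montage and optical constants.

The analysis operates on 29 signal types per subject:

* 18 fNIRS signals: chromophore concentration changes ([O2Hb], [HHb],
  [tHb]) averaged over three regions of interest (left prefrontal, right
  prefrontal, and left+right combined), each in a short-channel-corrected
  and an uncorrected ("raw") variant.
* 11 systemic physiological signals: heart rate (HR), mean arterial
  pressure (MAP), pulse pressure (PP), systolic and diastolic blood
  pressure (SBP, DBP), arterial oxygen saturation (SpO2), electrodermal
  activity and skin temperature on both wrists, and end-tidal CO2
  (PETCO2).

Every downstream stage (coherence, statistics, correlation matrices)
iterates over this registry in the fixed order defined here, so tables and
matrices written by different runs line up column-for-column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# sampling rates (Hz)

FNIRS_RATE = 7.81
PHYSIO_RATE = 4.0
CAPNO_RATE = 1.0

CHROMOPHORES = ("O2Hb", "HHb", "tHb")
ROIS = ("left", "right", "both")  # "both" = left + right combined
VARIANTS = ("corrected", "raw")


def fnirs_signal_name(chromophore: str, roi: str, variant: str = "corrected") -> str:
    """Canonical name of one of the 18 fNIRS signal types."""
    if chromophore not in CHROMOPHORES:
        raise ValueError(f"unknown chromophore {chromophore!r}")
    if roi not in ROIS:
        raise ValueError(f"unknown ROI {roi!r}")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    name = f"{chromophore}_{roi}"
    return name if variant == "corrected" else name + "_raw"


#: The 18 fNIRS signal types, corrected variants first within each ROI block.
FNIRS_SIGNALS: tuple[str, ...] = tuple(
    fnirs_signal_name(c, r, v) for r in ROIS for v in VARIANTS for c in CHROMOPHORES
)

#: The 11 systemic physiological signal types, in reporting order.
SYSTEMIC_SIGNALS: tuple[str, ...] = (
    "HR",
    "MAP",
    "PP",
    "SBP",
    "DBP",
    "SpO2",
    "EDA_left",
    "EDA_right",
    "Temp_left",
    "Temp_right",
    "PETCO2",
)

#: All 29 signal types in the stable registry order (fNIRS first).
SIGNAL_TYPES: tuple[str, ...] = FNIRS_SIGNALS + SYSTEMIC_SIGNALS


def signal_rate(signal_type: str) -> float:
    """Native sampling rate (Hz) of a registry signal type."""
    if signal_type in FNIRS_SIGNALS:
        return FNIRS_RATE
    if signal_type == "PETCO2":
        return CAPNO_RATE
    if signal_type in SYSTEMIC_SIGNALS:
        return PHYSIO_RATE
    raise KeyError(f"unknown signal type {signal_type!r}")


# ---------------------------------------------------------------------------
# frequency bands


@dataclass(frozen=True)
class FrequencyBand:
    """A named analysis band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError(f"require 0 < f_low < f_high, got {self}")

    def contains(self, freq: np.ndarray) -> np.ndarray:
        return (freq >= self.f_low) & (freq <= self.f_high)


#: Default band registry: very-low-frequency, two low-frequency bands and
#: the cardiac band.
BANDS: dict[str, FrequencyBand] = {
    "VLF": FrequencyBand("VLF", 0.002, 0.08),
    "LF1": FrequencyBand("LF1", 0.015, 0.15),
    "LF2": FrequencyBand("LF2", 0.08, 0.15),
    "HR": FrequencyBand("HR", 1.0, 2.0),
}

BAND_ORDER: tuple[str, ...] = ("VLF", "LF1", "LF2", "HR")


def band_signal_types(band_name: str) -> tuple[str, ...]:
    """Signal types analysable in a band.

    PETCO2 is sampled at 1 Hz; its Nyquist frequency (0.5 Hz) lies below
    the cardiac band, so PETCO2 is absent from the HR band. This is what
    makes the per-dyad series count (29 x 4) - 1 = 115.
    """
    if band_name == "HR":
        return tuple(s for s in SIGNAL_TYPES if s != "PETCO2")
    return SIGNAL_TYPES


# ---------------------------------------------------------------------------
# optical constants

#: Molar extinction coefficients, 1/(mM*cm), from the Kollias & Gratzer
#: hemoglobin compilation; rows = wavelengths, columns = (O2Hb, HHb).
EXTINCTION_COEFFS: dict[float, tuple[float, float]] = {
    760.0: (0.5864, 1.5485),
    850.0: (1.0580, 0.6913),
}

WAVELENGTHS: tuple[float, float] = (760.0, 850.0)

DEFAULT_DPF = 6.0


def extinction_matrix(
    wavelengths: tuple[float, float] = WAVELENGTHS,
    table: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    """2x2 extinction matrix E[lambda, chromophore] in 1/(mM*cm)."""
    table = EXTINCTION_COEFFS if table is None else table
    return np.array([table[w] for w in wavelengths], dtype=float)


# ---------------------------------------------------------------------------
# montage


@dataclass(frozen=True)
class Channel:
    """One source-detector channel of the optode montage."""

    index: int
    kind: str  # "long" or "short"
    roi: str  # "left" or "right"
    distance_cm: float
    paired_short: int | None = None  # nearest short channel (long only)


@dataclass(frozen=True)
class Montage:
    """Prefrontal montage: long (deep-sensitive) and short (scalp) channels.

    Long channels are 30 mm source-detector separations split evenly over
    the left and right prefrontal ROIs; short channels are 8 mm
    separations sensitive only to superficial tissue. Each long channel
    declares its nearest short channel, used by short-separation
    regression.
    """

    channels: tuple[Channel, ...]

    @property
    def long_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.kind == "long")

    @property
    def short_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.kind == "short")

    def roi_channels(self, roi: str) -> tuple[Channel, ...]:
        return tuple(c for c in self.long_channels if c.roi == roi)


def default_montage(n_long: int = 16, n_short: int = 8) -> Montage:
    """16 long (30 mm) + 8 short (8 mm) channels, half per hemisphere.

    Long channel i pairs with short channel i // (n_long // n_short).
    """
    if n_long <= 0 or n_short <= 0:
        raise ValueError("montage needs at least one long and one short channel")
    per_short = max(1, n_long // n_short)
    longs = tuple(
        Channel(
            index=i,
            kind="long",
            roi="left" if i < n_long // 2 else "right",
            distance_cm=3.0,
            paired_short=min(i // per_short, n_short - 1),
        )
        for i in range(n_long)
    )
    shorts = tuple(
        Channel(
            index=j,
            kind="short",
            roi="left" if j < n_short // 2 else "right",
            distance_cm=0.8,
        )
        for j in range(n_short)
    )
    return Montage(channels=longs + shorts)


# ---------------------------------------------------------------------------
# protocol


@dataclass(frozen=True)
class Protocol:
    """Session timeline: discarded prebaseline, then the two conditions."""

    prebaseline_s: float = 60.0
    eyes_closed_s: float = 600.0
    eye_contact_s: float = 600.0

    @property
    def session_s(self) -> float:
        return self.prebaseline_s + self.eyes_closed_s + self.eye_contact_s

    def segments(self) -> dict[str, tuple[float, float]]:
        t0 = self.prebaseline_s
        t1 = t0 + self.eyes_closed_s
        t2 = t1 + self.eye_contact_s
        return {
            "prebaseline": (0.0, t0),
            "eyes_closed": (t0, t1),
            "eye_contact": (t1, t2),
        }


CONDITIONS: tuple[str, str] = ("eyes_closed", "eye_contact")
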