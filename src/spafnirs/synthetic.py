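"""Synthetic dyad sessions with controllable cross-subject coupling.

The generator emulates a two-person hyperscanning recording: for each
subject, raw fNIRS intensities on a 16-long + 8-short channel prefrontal
montage at two wavelengths (7.81 Hz), plus 11 systemic physiological
signals (4 Hz, end-tidal CO2 at 1 Hz), over a 21-minute protocol
(1 min discarded prebaseline, 10 min eyes closed, 10 min eye contact).

Coupling model
--------------
Each generator-primitive signal type carries a latent decomposition

    x = s + n1,   y = s + n2

where ``s`` is a band-limited Gaussian process shared by the two subjects
and ``n1``, ``n2`` are independent band-limited noises with identical
spectra. The expected magnitude-squared coherence inside the band is

    C = shared_variance**2 / (shared_variance + idiosyncratic_variance)**2,

which makes every downstream coherence estimate checkable against a known
target. Condition and familiarity effects are variance gains applied to
the shared component only (eye-contact segment / familiar dyads), so they
map one-to-one onto the same formula.

fNIRS channels are synthesised in concentration space — a deep (cerebral)
component per chromophore and hemisphere carrying the cross-subject
coupling, plus a superficial scalp component shared between the long
channels and their co-located short channels — and passed through the
Beer-Lambert forward model to raw intensities. Short-separation
regression and the concentration conversion performed by the
preprocessing stage therefore operate on data with known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .registry import (
    CAPNO_RATE,
    BANDS,
    FNIRS_RATE,
    FrequencyBand,
    Montage,
    PHYSIO_RATE,
    Protocol,
    SYSTEMIC_SIGNALS,
    WAVELENGTHS,
    default_montage,
    extinction_matrix,
)

__all__ = [
    "LatentCouplingSpec",
    "CoModulationSpec",
    "GeneratorConfig",
    "SubjectRecording",
    "DyadSession",
    "band_limited_noise",
    "generate_coupled_band_pair",
    "forward_mbll",
    "generate_dyad",
    "generate_corpus",
    "save_session",
    "load_session",
]

#: Signal types the generator can inject coupling into directly. The
#: remaining registry types are derived (tHb sums, ROI averages, raw
#: variants) and inherit coupling from these.
PRIMITIVE_SIGNALS: tuple[str, ...] = (
    "O2Hb_left",
    "O2Hb_right",
    "HHb_left",
    "HHb_right",
    "tHb_left",
    "tHb_right",
) + SYSTEMIC_SIGNALS

#: Typical resting baselines added to systemic series (units of the
#: instrument: bpm, mmHg, %, microsiemens, degC, mmHg).
SYSTEMIC_BASELINES: dict[str, float] = {
    "HR": 70.0,
    "MAP": 90.0,
    "PP": 45.0,
    "SBP": 120.0,
    "DBP": 75.0,
    "SpO2": 98.0,
    "EDA_left": 2.0,
    "EDA_right": 2.0,
    "Temp_left": 33.0,
    "Temp_right": 33.0,
    "PETCO2": 40.0,
}


@dataclass(frozen=True)
class LatentCouplingSpec:
    """Coupling of one primitive signal type between the two subjects.

    ``condition_gain`` multiplies the shared-component variance during the
    eye-contact segment; ``group_gain`` multiplies it for familiar dyads
    (whole session). A spec for ``tHb_<roi>`` routes one common shared
    latent into both chromophores of that hemisphere so the coupling
    survives into the total-hemoglobin sum.
    """

    signal_type: str
    band: FrequencyBand
    shared_variance: float = 1.0
    idiosyncratic_variance: float = 1.0
    condition_gain: float = 1.0
    group_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.signal_type not in PRIMITIVE_SIGNALS:
            raise ValueError(
                f"{self.signal_type!r} is not generator-primitive; "
                f"choose one of {PRIMITIVE_SIGNALS}"
            )
        if self.shared_variance < 0 or self.idiosyncratic_variance < 0:
            raise ValueError("variances must be >= 0")
        if self.condition_gain < 0 or self.group_gain < 0:
            raise ValueError("gains must be >= 0")

    def expected_coherence(self) -> float:
        tot = self.shared_variance + self.idiosyncratic_variance
        return 0.0 if tot == 0 else (self.shared_variance / tot) ** 2


@dataclass(frozen=True)
class CoModulationSpec:
    """Slow common amplitude envelope on two signals' shared components.

    Makes the coupling strengths of ``signal_a`` and ``signal_b`` co-vary
    over time within one segment (optionally only for one familiarity
    group), which is what the correlated-coherence analysis detects.
    """

    signal_a: str
    signal_b: str
    segment: str = "eye_contact"
    group: str | None = None  # None = both groups
    depth: float = 0.8  # relative envelope excursion, 0..1

    def __post_init__(self) -> None:
        for s in (self.signal_a, self.signal_b):
            if s not in PRIMITIVE_SIGNALS:
                raise ValueError(f"{s!r} is not generator-primitive")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must be in [0, 1]")


def default_coupling_specs(
    shared: float = 1.0,
    idio: float = 1.0,
    condition_gain: float = 1.5,
    group_gain: float = 1.3,
) -> tuple[LatentCouplingSpec, ...]:
    """Study-condition defaults: every signal coupled at in-band coherence
    (shared/(shared+idio))**2 = 0.25, stronger during eye contact and in
    familiar dyads. HR couples in the cardiac band, everything else in LF1.
    """
    specs = []
    for st in ("O2Hb_left", "O2Hb_right", "HHb_left", "HHb_right"):
        specs.append(
            LatentCouplingSpec(
                st, BANDS["LF1"], 0.25 * shared, 0.25 * idio, condition_gain, group_gain
            )
        )
    for st in SYSTEMIC_SIGNALS:
        band = BANDS["HR"] if st == "HR" else BANDS["LF1"]
        specs.append(
            LatentCouplingSpec(st, band, shared, idio, condition_gain, group_gain)
        )
    return tuple(specs)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the dyad generator (defaults = the study protocol)."""

    session_duration: float = 1260.0
    prebaseline: float = 60.0
    segment_durations: tuple[float, float] = (600.0, 600.0)
    fnirs_rate: float = FNIRS_RATE
    physio_rate: float = PHYSIO_RATE
    capno_rate: float = CAPNO_RATE
    montage: Montage = field(default_factory=default_montage)
    coupling_spec: tuple[LatentCouplingSpec, ...] = field(
        default_factory=default_coupling_specs
    )
    comodulation: tuple[CoModulationSpec, ...] = ()
    # noise levels (fNIRS amplitudes in micromolar)
    deep_scale_um: float = 1.0  # sd multiplier: latent variances are in uM^2
    channel_noise_um: float = 0.05
    scalp_sd_um: float = 0.3
    superficial_weight: float = 0.5
    short_noise_um: float = 0.02
    physio_broadband: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.fnirs_rate, self.physio_rate, self.capno_rate):
            if r <= 0:
                raise ValueError("sampling rates must be > 0")
        total = self.prebaseline + sum(self.segment_durations)
        if abs(total - self.session_duration) > 1e-9:
            raise ValueError(
                f"prebaseline + segments = {total} s != session_duration "
                f"{self.session_duration} s"
            )
        if not self.montage.long_channels or not self.montage.short_channels:
            raise ValueError("montage must contain long and short channels")

    @property
    def protocol(self) -> Protocol:
        return Protocol(
            prebaseline_s=self.prebaseline,
            eyes_closed_s=self.segment_durations[0],
            eye_contact_s=self.segment_durations[1],
        )


@dataclass
class SubjectRecording:
    """Raw data of one subject: fNIRS intensities + systemic series."""

    fnirs_time: np.ndarray  # (n_samples,)
    fnirs_intensity: np.ndarray  # (n_channels, n_wavelengths, n_samples)
    physio: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (time, values)


@dataclass
class DyadSession:
    """One dyad's full recording plus protocol metadata and ground truth."""

    dyad_id: str
    familiarity: str  # "familiar" | "unfamiliar"
    subjects: tuple[SubjectRecording, SubjectRecording]
    config: GeneratorConfig
    ground_truth: tuple[LatentCouplingSpec, ...]
    seed: int

    @property
    def segments(self) -> dict[str, tuple[float, float]]:
        return self.config.protocol.segments()


# ---------------------------------------------------------------------------
# band-limited processes


def _clip_band(band: FrequencyBand, rate: float, margin: float = 0.97) -> FrequencyBand:
    """Clip a band's upper edge below Nyquist (used internally for 4 Hz
    signals whose cardiac band touches Nyquist exactly)."""
    nyq = rate / 2.0
    if band.f_low >= nyq * margin:
        raise ValueError(
            f"band {band.name} ({band.f_low}-{band.f_high} Hz) lies above the "
            f"Nyquist frequency {nyq} Hz at rate {rate} Hz"
        )
    if band.f_high < nyq * margin:
        return band
    return FrequencyBand(band.name, band.f_low, nyq * margin)


def band_limited_noise(
    n: int, rate: float, band: FrequencyBand, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian noise band-passed to ``band``.

    White noise through a zero-phase 4th-order Butterworth band-pass
    (applied forward-backward, i.e. 8 effective poles and >= 40 dB
    attenuation one octave into the stop band), then standardised so the
    realised sample variance is exactly 1.
    """
    nyq = rate / 2.0
    if not (0 < band.f_low < band.f_high < nyq):
        raise ValueError(
            f"band {band.f_low}-{band.f_high} Hz not inside (0, {nyq}) Hz"
        )
    white = rng.standard_normal(n)
    sos = sps.butter(4, [band.f_low / nyq, band.f_high / nyq], btype="band", output="sos")
    x = sps.sosfiltfilt(sos, white)
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate band-limited realisation (zero variance)")
    return x / sd


def generate_coupled_band_pair(
    duration: float,
    rate: float,
    band: FrequencyBand,
    shared_variance: float,
    idiosyncratic_variance: float,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Two series x = s + n1, y = s + n2 with known in-band coherence.

    The expected magnitude-squared coherence inside ``band`` is
    ``shared_variance**2 / (shared_variance + idiosyncratic_variance)**2``.

    Raises ``ValueError`` for a band at or above the Nyquist frequency or
    fewer than 64 samples.
    """
    n = int(round(duration * rate))
    if n < 64:
        raise ValueError(f"duration*rate = {n} samples; need >= 64")
    if band.f_high >= rate / 2.0:
        raise ValueError(
            f"band upper edge {band.f_high} Hz is not below Nyquist "
            f"{rate / 2.0} Hz; choose a narrower band or a higher rate"
        )
    if shared_variance < 0 or idiosyncratic_variance < 0:
        raise ValueError("variances must be >= 0")
    rng = np.random.default_rng(seed)
    s = n1 = n2 = np.zeros(n)
    if shared_variance > 0:
        s = band_limited_noise(n, rate, band, rng) * np.sqrt(shared_variance)
    else:
        rng.standard_normal(n)  # keep stream alignment regardless of variances
    if idiosyncratic_variance > 0:
        n1 = band_limited_noise(n, rate, band, rng) * np.sqrt(idiosyncratic_variance)
        n2 = band_limited_noise(n, rate, band, rng) * np.sqrt(idiosyncratic_variance)
    return s + n1, s + n2


def _slow_envelope(
    n: int, rate: float, depth: float, rng: np.random.Generator
) -> np.ndarray:
    """Positive slow amplitude envelope with mean ~1 (0.005-0.02 Hz)."""
    f_hi = min(0.02, 0.45 * rate)
    band = FrequencyBand("env", min(0.005, f_hi / 2), f_hi)
    z = band_limited_noise(n, rate, band, rng)
    return np.clip(1.0 + depth * z, 0.05, None)


# ---------------------------------------------------------------------------
# Beer-Lambert forward model


def forward_mbll(
    conc_changes_um: np.ndarray,
    ext_matrix: np.ndarray | None = None,
    distance_cm: float = 3.0,
    dpf: float = 6.0,
    baseline_intensity: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Raw intensities from chromophore concentration changes.

    Implements I_lambda(t) = I0_lambda * exp(-(E @ dc)_lambda * d * DPF)
    with ``conc_changes_um`` of shape (n_samples, 2) holding (d[O2Hb],
    d[HHb]) in micromolar and ``ext_matrix`` in 1/(mM*cm). Exact inverse
    of the optical-density -> concentration chain when the OD reference
    equals the baseline intensity.
    """
    E = extinction_matrix() if ext_matrix is None else np.asarray(ext_matrix, float)
    if E.shape != (2, 2) or abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("extinction matrix must be 2x2 and invertible")
    if distance_cm <= 0 or dpf <= 0:
        raise ValueError("distance and DPF must be > 0")
    dc_mM = np.asarray(conc_changes_um, float) * 1e-3
    if dc_mM.ndim != 2 or dc_mM.shape[1] != 2:
        raise ValueError("conc_changes_um must have shape (n_samples, 2)")
    od = dc_mM @ E.T * (distance_cm * dpf)  # (n_samples, 2)
    I0 = np.broadcast_to(np.atleast_1d(np.asarray(baseline_intensity, float)), (2,))
    return (I0 * np.exp(-od)).T  # (n_wavelengths, n_samples)


# ---------------------------------------------------------------------------
# dyad generation


def _segment_gain_profile(
    t: np.ndarray, protocol: Protocol, condition_gain: float, group_gain: float
) -> np.ndarray:
    """Amplitude multiplier over time: sqrt of the variance gain."""
    gain = np.full(t.shape, group_gain, float)
    a, b = protocol.segments()["eye_contact"]
    gain[(t >= a) & (t < b)] *= condition_gain
    return np.sqrt(gain)


def _latent_pairs(
    config: GeneratorConfig, familiar: bool, ss: np.random.SeedSequence
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Generate the coupled (x, y) pair for every primitive signal type.

    Returns unit-level latents (already scaled by the spec variances and
    segment/group gains). tHb specs emit entries for both chromophores of
    the hemisphere driven by one common shared latent.
    """
    protocol = config.protocol
    specs = {s.signal_type: s for s in config.coupling_spec}

    # one slow base envelope per comodulation spec, shared by its two
    # signals; sampled on a 4 Hz grid and interpolated to each native rate
    group_matches = lambda c: c.group is None or (c.group == "familiar") == familiar
    active_comods = [c for c in config.comodulation if group_matches(c)]
    env_seeds = ss.spawn(len(config.comodulation))
    base_rate = 4.0
    n_env = int(round(config.session_duration * base_rate))
    t_env = np.arange(n_env) / base_rate
    comod_of: dict[str, tuple[CoModulationSpec, np.ndarray]] = {}
    for c, es in zip(config.comodulation, env_seeds):
        if not group_matches(c):
            continue
        env = _slow_envelope(n_env, base_rate, c.depth, np.random.default_rng(es))
        comod_of[c.signal_a] = (c, env)
        comod_of[c.signal_b] = (c, env)

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    children = ss.spawn(len(PRIMITIVE_SIGNALS))
    for st, child in zip(PRIMITIVE_SIGNALS, children):
        spec = specs.get(st)
        if spec is None:
            continue
        if st in SYSTEMIC_SIGNALS:
            rate = config.capno_rate if st == "PETCO2" else config.physio_rate
        else:
            rate = config.fnirs_rate
        n = int(round(config.session_duration * rate))
        t = np.arange(n) / rate
        rng = np.random.default_rng(child)
        band = _clip_band(spec.band, rate)
        shared = band_limited_noise(n, rate, band, rng)
        amp = _segment_gain_profile(
            t, protocol, spec.condition_gain, spec.group_gain if familiar else 1.0
        )
        if st in comod_of:
            cm, base_env = comod_of[st]
            env = np.interp(t, t_env, base_env)
            a, b = protocol.segments()[cm.segment]
            env[~((t >= a) & (t < b))] = 1.0
            amp = amp * env
        s_scaled = shared * amp * np.sqrt(spec.shared_variance)
        sd_idio = np.sqrt(spec.idiosyncratic_variance)
        n1 = band_limited_noise(n, rate, band, rng) * sd_idio
        n2 = band_limited_noise(n, rate, band, rng) * sd_idio
        x, y = s_scaled + n1, s_scaled + n2
        if st.startswith("tHb_"):
            roi = st.split("_", 1)[1]
            # route the common latent into both chromophores (half each so
            # the tHb sum carries the spec'd shared variance)
            for chromo in ("O2Hb", "HHb"):
                out[f"{chromo}_{roi}"] = (x * 0.5, y * 0.5)
        else:
            out[st] = (x, y)
    return out


def generate_dyad(config: GeneratorConfig, dyad_id: str = "dyad00",
                  familiarity: str = "unfamiliar") -> DyadSession:
    """Synthesise one dyad session under ``config``.

    Deterministic given ``config.seed``: the same config yields
    bit-identical sessions.
    """
    if familiarity not in ("familiar", "unfamiliar"):
        raise ValueError("familiarity must be 'familiar' or 'unfamiliar'")
    ss = np.random.SeedSequence(config.seed)
    ss_latent, ss_a, ss_b = ss.spawn(3)
    latents = _latent_pairs(config, familiarity == "familiar", ss_latent)

    subjects = []
    for which, ss_subj in ((0, ss_a), (1, ss_b)):
        rng = np.random.default_rng(ss_subj)
        n_f = int(round(config.session_duration * config.fnirs_rate))
        t_f = np.arange(n_f) / config.fnirs_rate

        # deep chromophore components per hemisphere (uM)
        deep = {}
        for chromo in ("O2Hb", "HHb"):
            for roi in ("left", "right"):
                key = f"{chromo}_{roi}"
                if key in latents:
                    deep[(chromo, roi)] = latents[key][which] * config.deep_scale_um
                else:
                    deep[(chromo, roi)] = np.zeros(n_f)

        # superficial scalp component per chromophore, shared across channels
        scalp_band = FrequencyBand("scalp", 0.04, min(0.12, 0.45 * config.fnirs_rate))
        scalp = {
            chromo: band_limited_noise(n_f, config.fnirs_rate, scalp_band, rng)
            * config.scalp_sd_um
            for chromo in ("O2Hb", "HHb")
        }

        montage = config.montage
        n_ch = len(montage.channels)
        intensity = np.empty((n_ch, 2, n_f))
        E = extinction_matrix()
        for ci, ch in enumerate(montage.channels):
            conc = np.empty((n_f, 2))
            for k, chromo in enumerate(("O2Hb", "HHb")):
                noise = rng.standard_normal(n_f) * (
                    config.channel_noise_um if ch.kind == "long" else config.short_noise_um
                )
                if ch.kind == "long":
                    conc[:, k] = (
                        deep[(chromo, ch.roi)]
                        + config.superficial_weight * scalp[chromo]
                        + noise
                    )
                else:
                    conc[:, k] = scalp[chromo] + noise
            intensity[ci] = forward_mbll(
                conc, E, distance_cm=ch.distance_cm, dpf=6.0, baseline_intensity=1.0
            )

        physio: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for st in SYSTEMIC_SIGNALS:
            rate = config.capno_rate if st == "PETCO2" else config.physio_rate
            n_p = int(round(config.session_duration * rate))
            t_p = np.arange(n_p) / rate
            core = latents[st][which] if st in latents else np.zeros(n_p)
            broadband = rng.standard_normal(n_p) * config.physio_broadband
            physio[st] = (t_p, SYSTEMIC_BASELINES[st] + core + broadband)

        subjects.append(
            SubjectRecording(fnirs_time=t_f, fnirs_intensity=intensity, physio=physio)
        )

    return DyadSession(
        dyad_id=dyad_id,
        familiarity=familiarity,
        subjects=(subjects[0], subjects[1]),
        config=config,
        ground_truth=config.coupling_spec,
        seed=config.seed,
    )


def generate_corpus(
    n_dyads: int,
    config: GeneratorConfig | None = None,
    n_familiar: int | None = None,
    seed: int = 0,
) -> list[DyadSession]:
    """Generate a corpus of dyads, half familiar by default.

    Each dyad gets an independent seed derived from ``seed``.
    """
    base = GeneratorConfig() if config is None else config
    if n_familiar is None:
        n_familiar = n_dyads // 2
    child_seeds = np.random.SeedSequence(seed).generate_state(n_dyads) % (2**31)
    sessions = []
    for i in range(n_dyads):
        cfg = replace(base, seed=int(child_seeds[i]))
        fam = "familiar" if i < n_familiar else "unfamiliar"
        sessions.append(generate_dyad(cfg, dyad_id=f"dyad{i:02d}", familiarity=fam))
    return sessions


# ---------------------------------------------------------------------------
# on-disk format: SNIRF (fNIRS) + CSV per physio signal + JSON sidecar


def save_session(session: DyadSession, outdir: str | Path) -> Path:
    """Write a session as SNIRF + per-signal CSVs + a JSON sidecar."""
    from .snirfio import write_snirf

    outdir = Path(outdir) / session.dyad_id
    outdir.mkdir(parents=True, exist_ok=True)
    for si, subj in enumerate(session.subjects):
        tag = f"subj{si + 1}"
        write_snirf(
            outdir / f"{tag}.snirf",
            subj.fnirs_time,
            subj.fnirs_intensity,
            session.config.montage,
            WAVELENGTHS,
        )
        for name, (t, v) in subj.physio.items():
            arr = np.column_stack([t, v])
            np.savetxt(
                outdir / f"{tag}_{name}.csv",
                arr,
                delimiter=",",
                header="time_s,value",
                comments="",
            )
    sidecar = {
        "dyad_id": session.dyad_id,
        "familiarity": session.familiarity,
        "seed": session.seed,
        "segments": session.segments,
        "ground_truth": [
            {
                "signal_type": s.signal_type,
                "band": [s.band.name, s.band.f_low, s.band.f_high],
                "shared_variance": s.shared_variance,
                "idiosyncratic_variance": s.idiosyncratic_variance,
                "condition_gain": s.condition_gain,
                "group_gain": s.group_gain,
            }
            for s in session.ground_truth
        ],
    }
    (outdir / "session.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def load_session(indir: str | Path, config: GeneratorConfig | None = None) -> DyadSession:
    """Read a session written by :func:`save_session`."""
    from .snirfio import read_snirf

    indir = Path(indir)
    meta = json.loads((indir / "session.json").read_text())
    config = GeneratorConfig(seed=meta["seed"]) if config is None else config
    subjects = []
    for si in (1, 2):
        tag = f"subj{si}"
        t_f, intensity = read_snirf(indir / f"{tag}.snirf")
        physio = {}
        for st in SYSTEMIC_SIGNALS:
            arr = np.loadtxt(indir / f"{tag}_{st}.csv", delimiter=",", skiprows=1)
            physio[st] = (arr[:, 0], arr[:, 1])
        subjects.append(
            SubjectRecording(fnirs_time=t_f, fnirs_intensity=intensity, physio=physio)
        )
    gt = tuple(
        LatentCouplingSpec(
            g["signal_type"],
            FrequencyBand(*g["band"]),
            g["shared_variance"],
            g["idiosyncratic_variance"],
            g["condition_gain"],
            g["group_gain"],
        )
        for g in meta["ground_truth"]
    )
    return DyadSession(
        dyad_id=meta["dyad_id"],
        familiarity=meta["familiarity"],
        subjects=(subjects[0], subjects[1]),
        config=config,
        ground_truth=gt,
        seed=meta["seed"],
    )
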