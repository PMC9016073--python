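"""Minimal SNIRF (Shared Near Infrared Format, HDF5) read/write.

Covers the subset of SNIRF v1.0 this pipeline produces and consumes:
continuous-wave raw intensities (``dataType = 1``) with one data block,
a measurement list mapping columns to (channel, wavelength), and the
probe wavelengths. Channel ordering follows the montage: all channels at
wavelength 1 first, then all channels at wavelength 2.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .registry import Montage


def _str_dataset(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(
    path: str | Path,
    time: np.ndarray,
    intensity: np.ndarray,
    montage: Montage,
    wavelengths: tuple[float, ...],
) -> None:
    """Write raw intensities of shape (n_channels, n_wavelengths, n_samples)."""
    n_ch, n_wl, n_t = intensity.shape
    if n_wl != len(wavelengths):
        raise ValueError("wavelength axis does not match wavelength list")
    with h5py.File(path, "w") as f:
        _str_dataset(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _str_dataset(meta, "SubjectID", Path(path).stem)
        _str_dataset(meta, "MeasurementDate", "unknown")
        _str_dataset(meta, "MeasurementTime", "unknown")
        _str_dataset(meta, "LengthUnit", "cm")
        _str_dataset(meta, "TimeUnit", "s")
        _str_dataset(meta, "FrequencyUnit", "Hz")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, float))
        data = nirs.create_group("data1")
        # columns: wavelength-major, channel-minor
        dts = np.empty((n_t, n_ch * n_wl))
        col = 0
        for wi in range(n_wl):
            for ci in range(n_ch):
                dts[:, col] = intensity[ci, wi]
                col += 1
        data.create_dataset("dataTimeSeries", data=dts)
        data.create_dataset("time", data=np.asarray(time, float))
        col = 0
        for wi in range(n_wl):
            for ci, ch in enumerate(montage.channels):
                ml = data.create_group(f"measurementList{col + 1}")
                ml.create_dataset("sourceIndex", data=ci + 1)
                ml.create_dataset("detectorIndex", data=ci + 1)
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                col += 1


def read_snirf(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a SNIRF file written by :func:`write_snirf`.

    Returns (time, intensity) with intensity of shape
    (n_channels, n_wavelengths, n_samples).
    """
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        time = np.asarray(data["time"])
        dts = np.asarray(data["dataTimeSeries"])
        n_cols = dts.shape[1]
        ml_keys = [k for k in data.keys() if k.startswith("measurementList")]
        if len(ml_keys) != n_cols:
            raise ValueError("measurement list does not match data columns")
        chan_idx = np.empty(n_cols, int)
        wl_idx = np.empty(n_cols, int)
        for k in ml_keys:
            col = int(k[len("measurementList"):]) - 1
            ml = data[k]
            chan_idx[col] = int(ml["sourceIndex"][()]) - 1
            wl_idx[col] = int(ml["wavelengthIndex"][()]) - 1
        n_ch = chan_idx.max() + 1
        n_wl = wl_idx.max() + 1
        intensity = np.empty((n_ch, n_wl, dts.shape[0]))
        for col in range(n_cols):
            intensity[chan_idx[col], wl_idx[col]] = dts[:, col]
    return time, intensity
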