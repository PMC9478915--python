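"""File formats: recordings, metadata, detection/identity tables, configs.

Conventions
-----------
* times are seconds from recording start (float), electrodes 0-based,
  frequencies in Hz, powers in dB re 1 mV^2/Hz;
* recordings are multichannel WAV (float32 or int16) or flat binary
  (channel-interleaved int16/float32) accompanied by a YAML metadata file
  with samplerate, channel count, dtype, and electrode coordinates;
* tables are TSV with headers; the identity table round-trips against the
  detection table via the (time_index, eodf_hz) key.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .simulate import ArraySpec
from .spectral import Detection
from .tracker import IdentityTrace

__all__ = [
    "write_recording",
    "read_recording",
    "write_detections",
    "read_detections",
    "write_identities",
    "read_identities",
    "traces_from_tables",
    "write_calibration",
    "read_calibration",
    "write_report",
]

#: scale used when quantizing float mV samples to int16
INT16_SCALE = 2000.0


def write_recording(path: str | Path, samples: np.ndarray, array: ArraySpec,
                    dtype: str = "float32") -> Path:
    """Write a multichannel recording plus its YAML metadata sidecar.

    ``path`` ending in ``.wav`` writes a WAV file; any other suffix writes
    flat channel-interleaved binary.  Returns the metadata path
    (``<path>.yaml``).
    """
    path = Path(path)
    samples = np.asarray(samples)
    if dtype == "int16":
        data = np.clip(np.round(samples * INT16_SCALE), -32768, 32767).astype(np.int16)
    elif dtype == "float32":
        data = samples.astype(np.float32)
    else:
        raise ValueError("dtype must be 'int16' or 'float32'")
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(array.samplerate), data.T.copy())
    else:
        data.T.reshape(-1).tofile(path)
    meta = {
        "samplerate": float(array.samplerate),
        "n_electrodes": int(array.n_electrodes),
        "dtype": dtype,
        "scale_mv": 1.0 if dtype == "float32" else 1.0 / INT16_SCALE,
        "electrode_positions": [
            [float(x), float(y)] for x, y in array.electrode_positions
        ],
    }
    meta_path = path.with_suffix(path.suffix + ".yaml")
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    return meta_path


def read_recording(path: str | Path, meta_path: str | Path | None = None
                   ) -> tuple[np.ndarray, ArraySpec]:
    """Read a recording written by :func:`write_recording`.

    Returns (samples, array) with samples in mV, shape
    (n_electrodes, n_samples).  The file layout is validated against the
    metadata.
    """
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_suffix(path.suffix + ".yaml")
    meta_path = Path(meta_path)
    if not path.exists():
        raise FileNotFoundError(f"recording file {path} not found")
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata file {meta_path} not found")
    meta = yaml.safe_load(meta_path.read_text())
    n_ch = int(meta["n_electrodes"])
    dtype = np.int16 if meta["dtype"] == "int16" else np.float32
    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        if rate != int(meta["samplerate"]):
            raise ValueError("samplerate mismatch between WAV header and metadata")
        if data.ndim == 1:
            data = data[:, None]
        if data.shape[1] != n_ch:
            raise ValueError(
                f"metadata promises {n_ch} channels, WAV holds {data.shape[1]}"
            )
        samples = data.T
    else:
        flat = np.fromfile(path, dtype=dtype)
        if flat.size == 0 or flat.size % n_ch != 0:
            raise ValueError(
                f"binary file size {flat.size} not divisible by {n_ch} channels"
            )
        samples = flat.reshape(-1, n_ch).T
    if samples.dtype == np.int16:
        samples = samples.astype(np.float32) * float(meta.get("scale_mv", 1.0))
    else:
        samples = samples.astype(np.float32)
    array = ArraySpec(
        electrode_positions=np.array(meta["electrode_positions"], dtype=float),
        samplerate=float(meta["samplerate"]),
    )
    return samples, array


def write_detections(path: str | Path, detections: list[Detection]) -> None:
    """Write the detection table (TSV): time_index, time_s, eodf_hz, power_db_<e>."""
    n_el = len(detections[0].powers) if detections else 0
    cols = ["time_index", "time_s", "eodf_hz"] + [f"power_db_{e}" for e in range(n_el)]
    rows = [
        [d.time_index, d.time, d.eodf, *np.asarray(d.powers, dtype=float)]
        for d in detections
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_detections(path: str | Path) -> list[Detection]:
    """Read a detection table written by :func:`write_detections`."""
    df = pd.read_csv(path, sep="\t")
    power_cols = [c for c in df.columns if c.startswith("power_db_")]
    return [
        Detection(
            time_index=int(row.time_index),
            time=float(row.time_s),
            eodf=float(row.eodf_hz),
            powers=np.array([getattr(row, c) for c in power_cols], dtype=float),
        )
        for row in df.itertuples(index=False)
    ]


def write_identities(path: str | Path, traces: list[IdentityTrace]) -> None:
    """Write the identity table (TSV): identity_id, time_index, time_s, eodf_hz."""
    rows = [
        [tr.identity_id, d.time_index, d.time, d.eodf]
        for tr in sorted(traces, key=lambda t: t.identity_id)
        for d in tr.detections
    ]
    pd.DataFrame(rows, columns=["identity_id", "time_index", "time_s", "eodf_hz"]
                 ).to_csv(path, sep="\t", index=False)


def read_identities(path: str | Path) -> pd.DataFrame:
    """Read an identity table as a DataFrame."""
    return pd.read_csv(path, sep="\t")


def traces_from_tables(identities: pd.DataFrame,
                       detections: list[Detection]) -> list[IdentityTrace]:
    """Rebuild identity traces from an identity table and the detection list.

    Detections are matched by the (time_index, eodf_hz) key, which is unique
    per detection; unknown keys raise an error.
    """
    lookup = {(d.time_index, round(d.eodf, 6)): i for i, d in enumerate(detections)}
    traces: dict[int, IdentityTrace] = {}
    for row in identities.itertuples(index=False):
        key = (int(row.time_index), round(float(row.eodf_hz), 6))
        if key not in lookup:
            raise KeyError(f"identity table row {key} not found among detections")
        idx = lookup[key]
        tr = traces.setdefault(int(row.identity_id),
                               IdentityTrace(int(row.identity_id)))
        tr.detections.append(detections[idx])
        tr.indices.append(idx)
    out = []
    for tr in traces.values():
        order = np.argsort([d.time for d in tr.detections], kind="stable")
        tr.detections = [tr.detections[i] for i in order]
        tr.indices = [tr.indices[i] for i in order]
        out.append(tr)
    out.sort(key=lambda t: t.identity_id)
    return out


def write_calibration(path: str | Path, sorted_differences: np.ndarray) -> None:
    """Serialize a field-error calibration as a single-column TSV."""
    pd.DataFrame({"field_difference": np.asarray(sorted_differences)}
                 ).to_csv(path, sep="\t", index=False)


def read_calibration(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["field_difference"].to_numpy()


def write_report(path: str | Path, report: dict) -> None:
    """Write an evaluation report as JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
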