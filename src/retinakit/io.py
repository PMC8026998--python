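"""Serialization of the shared data model.

Voltage traces travel as HDF5 (dataset ``voltage``, channels × samples
float32, with ``sampling_rate_hz`` and ``channel_pitch_um`` attributes);
everything tabular is tab-delimited UTF-8 text with a header row and
6-significant-digit float formatting; stimulus protocols are YAML or JSON
lists of flash epochs.  All writers are deterministic given their inputs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .mea import RawRecording, default_geometry
from .synth import StimulusProtocol

__all__ = [
    "read_recording",
    "write_recording",
    "read_protocol",
    "write_protocol",
    "read_table",
    "write_table",
    "read_counts_matrix",
    "write_counts_matrix",
]

FLOAT_FMT = "%.6g"

#: Required columns and nonnegative-value constraints per table kind.
TABLE_SCHEMAS: dict[str, dict] = {
    "spikes": {"columns": ["channel_id", "t_s"], "nonnegative": ["t_s"]},
    "trial_counts": {
        "columns": ["channel_id", "intensity", "rep_index", "count_on", "count_off", "count_spont"],
        "nonnegative": ["count_on", "count_off", "count_spont"],
    },
    "survival": {
        "columns": ["animal_id", "arm", "eye", "age_pn", "position_deg", "cones_per_100um"],
        "nonnegative": ["cones_per_100um", "age_pn"],
    },
    "classification": {
        "columns": ["channel_id", "n_photopic_activated", "included"],
        "nonnegative": ["n_photopic_activated"],
    },
    "ratios": {
        "columns": ["channel_id", "intensity", "rate_on", "rate_spont", "ratio"],
        "nonnegative": ["rate_on", "rate_spont"],
    },
    "qpcr": {
        "columns": ["sample_id", "group", "ct_target", "ct_reference"],
        "nonnegative": ["ct_target", "ct_reference"],
    },
    "de_table": {"columns": ["gene_id", "t", "mean_log2_diff", "significant"], "nonnegative": []},
}


def write_recording(rec: RawRecording, path) -> None:
    pitch = 200.0
    if rec.geometry is not None and "pitch_um" in rec.geometry:
        pitch = float(rec.geometry["pitch_um"].iloc[0])
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("voltage", data=rec.voltage.astype(np.float32))
        ds.attrs["units"] = "volts"
        f.attrs["sampling_rate_hz"] = float(rec.sampling_rate)
        f.attrs["channel_pitch_um"] = pitch
        f.create_dataset("channel_ids", data=np.asarray(rec.channel_ids, dtype=np.int64))


def read_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        if "voltage" not in f:
            raise KeyError("missing dataset 'voltage'")
        if "sampling_rate_hz" not in f.attrs:
            raise KeyError("missing attribute 'sampling_rate_hz'")
        voltage = f["voltage"][...]
        if voltage.ndim != 2 or voltage.shape[0] == 0:
            raise ValueError("'voltage' must be a nonempty channels x samples matrix")
        rate = float(f.attrs["sampling_rate_hz"])
        pitch = float(f.attrs.get("channel_pitch_um", 200.0))
        if "channel_ids" in f:
            ids = tuple(int(i) for i in f["channel_ids"][...])
        else:
            ids = tuple(range(voltage.shape[0]))
    return RawRecording(
        voltage=voltage,
        sampling_rate=rate,
        channel_ids=ids,
        geometry=default_geometry(voltage.shape[0], pitch_um=pitch),
    )


def write_protocol(protocol: StimulusProtocol, path) -> None:
    path = Path(path)
    payload = {"dark_gap_s": protocol.dark_gap_s, "epochs": protocol.to_records()}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


def read_protocol(path) -> StimulusProtocol:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return StimulusProtocol.from_records(payload["epochs"], dark_gap_s=payload.get("dark_gap_s"))


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    schema = TABLE_SCHEMAS[kind]
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table missing columns {missing}")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path, kind: str) -> pd.DataFrame:
    schema = TABLE_SCHEMAS[kind]
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table missing columns {missing}")
    extra = [c for c in df.columns if c not in schema["columns"]]
    if extra:
        warnings.warn(f"{kind} table carries extra columns {extra}; preserved", stacklevel=2)
    for col in schema["nonnegative"]:
        vals = df[col].dropna()
        if (vals < 0).any():
            raise ValueError(f"negative values in column {col!r} of {kind} table")
    key_cols = {
        "survival": ["animal_id", "arm", "eye", "age_pn", "position_deg"],
        "classification": ["channel_id"],
    }.get(kind)
    if key_cols and df.duplicated(subset=key_cols).any():
        raise ValueError(f"duplicate keys {key_cols} in {kind} table")
    return df


def write_counts_matrix(counts: pd.DataFrame, path) -> None:
    """Genes × samples count matrix; first column is the gene id."""
    counts.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


def read_counts_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    return df
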