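"""Reading and writing sessions and intermediate results.

The native signal container is HDF5 (float64, lossless); events and
channel metadata travel as tab-separated tables following BIDS-iEEG
column conventions (``onset``/``trial_type`` and ``name``/``group``).
EDF import is supported for interoperability; EDF's 16-bit quantization
is accepted as lossy.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (
    ContactInfo,
    EpochedPower,
    EventTable,
    FeatureSet,
    RecordingSession,
    SessionValidationError,
)

SIGNAL_FILENAME = "session.h5"
EVENTS_FILENAME = "events.tsv"
CHANNELS_FILENAME = "channels.tsv"


def write_session(session: RecordingSession, out_dir) -> dict:
    """Write a session to ``out_dir``; returns the emitted file paths.

    Layout: ``session.h5`` holds /signals (contacts x samples, float64)
    with ``fs`` and a JSON meta attribute; ``events.tsv`` and
    ``channels.tsv`` carry events and contact metadata.  Output bytes are
    deterministic for a fixed input.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    session.validate()

    sig_path = out_dir / SIGNAL_FILENAME
    with h5py.File(sig_path, "w") as f:
        dset = f.create_dataset("signals", data=session.signals, dtype="float64")
        dset.attrs["units"] = "uV"
        f.attrs["fs"] = float(session.fs)
        f.attrs["session_meta"] = json.dumps(session.session_meta, sort_keys=True)

    ev = session.events.df
    events_df = pd.DataFrame(
        {
            "onset": ev["onset_sample"] / session.fs,
            "duration": session.stimulus_ms / 1000.0,
            "trial_type": ev["class_label"],
            "modality": ev["modality"],
            "onset_sample": ev["onset_sample"],
        }
    )
    ev_path = out_dir / EVENTS_FILENAME
    events_df.to_csv(ev_path, sep="\t", index=False, float_format="%.9g")

    rows = []
    for c in session.contacts:
        xyz = c.mni_xyz if c.mni_xyz is not None else [np.nan] * 3
        rows.append(
            {
                "name": c.contact_id,
                "group": c.shaft_id,
                "index_on_shaft": c.index_on_shaft,
                "region": c.region_label,
                "hemisphere": c.hemisphere,
                "x": xyz[0],
                "y": xyz[1],
                "z": xyz[2],
                "status": "bad" if c.excluded else "good",
                "status_description": c.exclusion_reason,
            }
        )
    ch_path = out_dir / CHANNELS_FILENAME
    pd.DataFrame(rows).to_csv(ch_path, sep="\t", index=False, float_format="%.9g")
    return {"signals": sig_path, "events": ev_path, "channels": ch_path}


def _read_signals_h5(path: Path):
    with h5py.File(path, "r") as f:
        signals = np.asarray(f["signals"], dtype=np.float64)
        fs = float(f.attrs["fs"])
        meta = json.loads(f.attrs.get("session_meta", "{}"))
    return signals, fs, meta


def _read_signals_edf(path: Path):
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ImportError(
            "EDF import requires the optional dependency 'mne' "
            "(pip install seegdecode[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), {}


def read_session(signal_path, events_path=None, channels_path=None) -> RecordingSession:
    """Read and validate a session from disk.

    ``signal_path`` may be the native HDF5 container or an EDF file.
    ``events_path``/``channels_path`` default to sibling ``events.tsv`` /
    ``channels.tsv`` files.
    """
    signal_path = Path(signal_path)
    if events_path is None:
        events_path = signal_path.parent / EVENTS_FILENAME
    if channels_path is None:
        channels_path = signal_path.parent / CHANNELS_FILENAME

    suffix = signal_path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        signals, fs, meta = _read_signals_h5(signal_path)
    elif suffix == ".edf":
        signals, fs, meta = _read_signals_edf(signal_path)
    else:
        raise ValueError(f"unsupported signal container: {signal_path.name}")

    events_df = pd.read_csv(events_path, sep="\t")
    for col in ("onset", "trial_type"):
        if col not in events_df.columns:
            raise SessionValidationError(f"{events_path}: missing column {col!r}")
    if "onset_sample" in events_df.columns:
        onsets = events_df["onset_sample"].to_numpy(dtype=np.int64)
    else:
        onsets = np.round(events_df["onset"].to_numpy(dtype=float) * fs).astype(np.int64)
    modality = (
        events_df["modality"]
        if "modality" in events_df.columns
        else meta.get("modality", "auditory")
    )
    events = EventTable.from_arrays(onsets, events_df["trial_type"], modality)

    channels_df = pd.read_csv(channels_path, sep="\t")
    for col in ("name", "group"):
        if col not in channels_df.columns:
            raise SessionValidationError(f"{channels_path}: missing column {col!r}")
    contacts = []
    for i, row in channels_df.iterrows():
        xyz = None
        if {"x", "y", "z"} <= set(channels_df.columns):
            vals = [row["x"], row["y"], row["z"]]
            if not any(pd.isna(v) for v in vals):
                xyz = np.asarray(vals, dtype=float)
        contacts.append(
            ContactInfo(
                contact_id=str(row["name"]),
                shaft_id=str(row["group"]),
                index_on_shaft=int(row.get("index_on_shaft", i + 1)),
                region_label=str(row.get("region", "unknown")),
                hemisphere=str(row.get("hemisphere", "left")),
                mni_xyz=xyz,
                excluded=str(row.get("status", "good")) == "bad",
                exclusion_reason=str(row.get("status_description", "none")),
            )
        )

    session = RecordingSession(
        signals=signals, fs=fs, contacts=contacts, events=events, session_meta=meta
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# Intermediate results (epochs, features) for CLI chaining


def _write_contacts_group(f: h5py.File, contacts) -> None:
    grp = f.create_group("contacts")
    str_dt = h5py.string_dtype()
    for name, getter in (
        ("contact_id", lambda c: c.contact_id),
        ("shaft_id", lambda c: c.shaft_id),
        ("region_label", lambda c: c.region_label),
        ("hemisphere", lambda c: c.hemisphere),
        ("exclusion_reason", lambda c: c.exclusion_reason),
    ):
        grp.create_dataset(name, data=[getter(c) for c in contacts], dtype=str_dt)
    grp.create_dataset(
        "index_on_shaft", data=[c.index_on_shaft for c in contacts], dtype="int64"
    )
    grp.create_dataset("excluded", data=[c.excluded for c in contacts], dtype="bool")


def _read_contacts_group(f: h5py.File) -> list[ContactInfo]:
    grp = f["contacts"]
    decode = lambda arr: [x.decode() if isinstance(x, bytes) else str(x) for x in arr]
    ids = decode(grp["contact_id"][()])
    shafts = decode(grp["shaft_id"][()])
    regions = decode(grp["region_label"][()])
    hemis = decode(grp["hemisphere"][()])
    reasons = decode(grp["exclusion_reason"][()])
    idx = grp["index_on_shaft"][()]
    excl = grp["excluded"][()]
    return [
        ContactInfo(
            contact_id=ids[i],
            shaft_id=shafts[i],
            index_on_shaft=int(idx[i]),
            region_label=regions[i],
            hemisphere=hemis[i],
            excluded=bool(excl[i]),
            exclusion_reason=reasons[i],
        )
        for i in range(len(ids))
    ]


def save_epoched(ep: EpochedPower, path) -> Path:
    path = Path(path)
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.create_dataset("z_power", data=ep.z_power)
        f.create_dataset("baseline_power", data=ep.baseline_power)
        f.create_dataset("raw_power", data=ep.raw_power)
        f.create_dataset("labels", data=[str(x) for x in ep.labels], dtype=str_dt)
        f.create_dataset("log", data=[str(x) for x in ep.log], dtype=str_dt)
        f.attrs["fs"] = float(ep.fs)
        _write_contacts_group(f, ep.contacts)
    return path


def load_epoched(path) -> EpochedPower:
    with h5py.File(path, "r") as f:
        decode = lambda arr: [
            x.decode() if isinstance(x, bytes) else str(x) for x in arr
        ]
        return EpochedPower(
            z_power=f["z_power"][()],
            baseline_power=f["baseline_power"][()],
            raw_power=f["raw_power"][()],
            labels=np.asarray(decode(f["labels"][()]), dtype=object),
            fs=float(f.attrs["fs"]),
            contacts=_read_contacts_group(f),
            log=decode(f["log"][()]),
        )


def save_features(fs: FeatureSet, path) -> Path:
    path = Path(path)
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=fs.matrix)
        f.create_dataset(
            "contact_ids", data=[str(x) for x in fs.contact_ids], dtype=str_dt
        )
        f.create_dataset("bin_index", data=fs.bin_index)
        f.create_dataset("labels", data=[str(x) for x in fs.labels], dtype=str_dt)
        f.attrs["bin_ms"] = fs.bin_ms
        for name in ("r_values", "p_values"):
            arr = getattr(fs, name)
            if arr is not None:
                f.create_dataset(name, data=np.asarray(arr, dtype=float))
        if fs.selected is not None:
            f.create_dataset("selected", data=np.asarray(fs.selected, dtype=bool))
        if fs.n_significant is not None:
            f.attrs["n_significant"] = int(fs.n_significant)
        if fs.bonferroni_alpha is not None:
            f.attrs["bonferroni_alpha"] = float(fs.bonferroni_alpha)
    return path


def load_features(path) -> FeatureSet:
    with h5py.File(path, "r") as f:
        decode = lambda arr: [
            x.decode() if isinstance(x, bytes) else str(x) for x in arr
        ]
        kwargs = {}
        for name in ("r_values", "p_values"):
            if name in f:
                kwargs[name] = f[name][()]
        if "selected" in f:
            kwargs["selected"] = f["selected"][()]
        if "n_significant" in f.attrs:
            kwargs["n_significant"] = int(f.attrs["n_significant"])
        if "bonferroni_alpha" in f.attrs:
            kwargs["bonferroni_alpha"] = float(f.attrs["bonferroni_alpha"])
        return FeatureSet(
            matrix=f["matrix"][()],
            contact_ids=np.asarray(decode(f["contact_ids"][()]), dtype=object),
            bin_index=f["bin_index"][()],
            labels=np.asarray(decode(f["labels"][()]), dtype=object),
            bin_ms=float(f.attrs["bin_ms"]),
            **kwargs,
        )
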