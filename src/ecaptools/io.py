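"""Recording bundles on disk and pipeline configuration files.

A recording bundle is a directory holding ``samples.npy`` (channel x time,
float64), a JSON sidecar ``meta.json`` (sampling rate, units, per-channel
electrode metadata) and, when a stimulation train exists, ``events.csv``
(onset_s, amplitude_ma, pulse_width_us).  A delimited-text variant
(``samples.tsv``) is supported for interoperability.  Samples are written
in microvolts with the unit declared in the sidecar — a lossless round
trip of the in-memory representation; volt-scaled files are read
transparently via the sidecar's ``units`` field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .types import ElectrodeSpec, StimulationTrain, TimeSeriesRecording

UV_PER_V = 1e6


def write_bundle(rec: TimeSeriesRecording, path, text: bool = False) -> Path:
    """Write a recording bundle directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if text:
        np.savetxt(path / "samples.tsv", rec.samples.T, delimiter="\t")
    else:
        np.save(path / "samples.npy", rec.samples)
    meta = {
        "sampling_rate": rec.sampling_rate,
        "units": "uV",
        "n_channels": len(rec.channels),
        "n_samples": rec.n_samples,
        "format": "tsv" if text else "npy",
        "channels": [dataclasses.asdict(ch) for ch in rec.channels],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    if rec.events is not None:
        pd.DataFrame(
            {
                "onset_s": rec.events.onsets_s,
                "amplitude_ma": rec.events.amplitude_ma,
                "pulse_width_us": rec.events.pulse_width_us,
            }
        ).to_csv(path / "events.csv", index=False)
    return path


def read_bundle(path) -> TimeSeriesRecording:
    """Read a recording bundle back into memory (uV internally).

    Rejects a missing sidecar, a channel-count mismatch between sidecar and
    samples, and non-monotone event onsets — each with a named error.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("format") == "tsv":
        samples = np.atleast_2d(np.loadtxt(path / "samples.tsv", delimiter="\t").T)
    else:
        samples = np.load(path / "samples.npy")
    if samples.shape[0] != meta["n_channels"]:
        raise ValueError(
            f"sidecar claims {meta['n_channels']} channels, samples file has "
            f"{samples.shape[0]}"
        )
    units = meta.get("units", "uV")
    if units == "V":
        samples = samples * UV_PER_V
    elif units != "uV":
        raise ValueError(f"unknown sample units {units!r}")
    channels = [ElectrodeSpec(**ch) for ch in meta["channels"]]
    events = None
    events_path = path / "events.csv"
    if events_path.exists():
        ev = pd.read_csv(events_path)
        onsets = ev["onset_s"].to_numpy(dtype=float)
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets are not strictly increasing")
        events = StimulationTrain(
            onsets,
            amplitude_ma=float(ev["amplitude_ma"].iloc[0]),
            pulse_width_us=float(ev["pulse_width_us"].iloc[0]),
        )
    return TimeSeriesRecording(
        samples=samples,
        sampling_rate=float(meta["sampling_rate"]),
        channels=channels,
        events=events,
    )


def load_config_file(path) -> dict:
    """Load a YAML or JSON pipeline/simulation config document."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        return yaml.safe_load(text)
    return json.loads(text)


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping for run logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
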