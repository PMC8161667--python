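"""File formats: EDF export, event tables, config files.

Continuous simulated EEG is exported as plain European Data Format
(EDF, 16-bit): one 1-second data record per elapsed second, per-channel
physical scaling, final record zero-padded.  Events travel alongside as
a BIDS-flavoured tab-separated table (onset_sample, onset_ms, label,
train_index).  Pipeline configuration is a single YAML document.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SimulatedRecording

EVENT_COLUMNS = ["onset_sample", "onset_ms", "label", "train_index"]


def _field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        if isinstance(value, float):
            s = f"{value:.{max(1, width - 6)}g}"
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: SimulatedRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF.

    Record duration is 1 s, so the sample rate must be an integer
    number of samples per second; the final partial record is padded
    with zeros (the event table carries the true sample count).
    """
    path = Path(path)
    sr = rec.sample_rate
    if abs(sr - round(sr)) > 1e-9:
        raise ValueError("EDF export requires an integer sample rate")
    spr = int(round(sr))
    n_ch, n_samp = rec.data.shape
    n_records = int(np.ceil(n_samp / spr))

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    flat = phys_max - phys_min < 1e-9
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)

    header = b"".join(
        [
            _field(0, 8),
            _field(rec.subject_id, 80),
            _field(f"group={rec.group} age={rec.age_months}m seed={rec.seed}", 80),
            _field("01.01.26", 8),
            _field("00.00.00", 8),
            _field(256 + 256 * n_ch, 8),
            _field("", 44),
            _field(n_records, 8),
            _field(1, 8),
            _field(n_ch, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(ch, 16) for ch in rec.ch_names),
            b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{v:.6g}"[:8], 8) for v in phys_min),
            b"".join(_field(f"{v:.6g}"[:8], 8) for v in phys_max),
            b"".join(_field(dig_min, 8) for _ in range(n_ch)),
            b"".join(_field(dig_max, 8) for _ in range(n_ch)),
            b"".join(_field("BP 0.1-30Hz (sim)", 80) for _ in range(n_ch)),
            b"".join(_field(spr, 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )

    # re-read the truncated physical extremes so scaling matches the header
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    scale = (pmax - pmin) / (dig_max - dig_min)

    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samp] = rec.data
    digital = np.round(
        (padded - pmin[:, None]) / scale[:, None] + dig_min
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    events = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event file {path} is missing columns {missing}")
    return events


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
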