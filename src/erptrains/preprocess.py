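"""Continuous EEG -> per-subject condition-average ERPs.

Stages: zero-phase 0.1-30 Hz band-pass; segmentation into -100..+800 ms
epochs (inclusive endpoints, 451 samples at 500 Hz); deterministic
peak-to-peak artifact detection (epochs with more than ``bad_channel_limit``
bad channels are rejected, remaining bad channels interpolated from
neighbours); baseline correction over -100..0 ms followed by average
re-referencing; truncation to the first N retained trials per condition
(standards 120, deviants 65) and averaging, with per-condition exclusion
of subjects retaining fewer than ``min_trials`` trials.

The amplitude criterion replaces the visual artifact inspection used
with real infant data: a reproducible pipeline needs a deterministic
rule.  Bad-channel interpolation uses inverse-distance-weighted
neighbour averages on the schematic montage; spherical splines would
be the choice for a real high-density net.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import Montage
from .simulate import CONDITIONS, DEVIANTS, STANDARDS, SimulatedRecording

REASON_EDGE = "edge"
REASON_TOO_MANY_BAD = "too_many_bad_channels"
REASON_UNINTERPOLABLE = "uninterpolable"
REASON_OVER_CAP = "over_cap"


@dataclass(frozen=True)
class PreprocConfig:
    band: tuple[float, float] = (0.1, 30.0)
    filter_order: int = 4
    epoch_window: tuple[float, float] = (-100.0, 800.0)  # ms
    baseline_window: tuple[float, float] = (-100.0, 0.0)  # ms
    bad_channel_limit: int = 25          # reject epoch if MORE than this many bad
    ptp_threshold: float = 200.0         # uV peak-to-peak per channel
    min_trials: int = 10
    cap_standards: int = 120
    cap_deviants: int = 65
    min_good_neighbours: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band corners must satisfy 0 < low < high")
        if self.baseline_window[0] < self.epoch_window[0] or (
            self.baseline_window[1] > self.epoch_window[1]
        ):
            raise ValueError("baseline window must lie inside the epoch window")
        if min(self.cap_standards, self.cap_deviants) <= self.min_trials:
            raise ValueError("truncation caps must exceed min_trials")
        if self.ptp_threshold <= 0:
            raise ValueError("ptp_threshold must be positive")

    def cap_for(self, condition: str) -> int:
        return self.cap_deviants if condition in DEVIANTS else self.cap_standards


@dataclass
class EpochSet:
    """Per-trial segments for one subject, with rejection bookkeeping."""

    epochs: dict[str, np.ndarray]            # condition -> (trials, channels, samples)
    keep: dict[str, np.ndarray]              # condition -> bool per trial
    reject_reason: dict[str, list[str | None]]
    bad_channels: dict[str, list[list[int]]]  # per condition, per trial
    times: np.ndarray                        # ms relative to stimulus onset
    ch_names: tuple[str, ...]
    sample_rate: float
    n_presented: dict[str, int] = field(default_factory=dict)

    def retained(self, condition: str) -> np.ndarray:
        return self.epochs[condition][self.keep[condition]]

    def retention_summary(self) -> dict[str, dict[str, int]]:
        """presented = retained + rejected, per condition."""
        out = {}
        for cond in self.epochs:
            kept = int(self.keep[cond].sum())
            out[cond] = {
                "presented": self.n_presented.get(cond, len(self.keep[cond])),
                "retained": kept,
                "rejected": self.n_presented.get(cond, len(self.keep[cond])) - kept,
            }
        return out


@dataclass
class ConditionERP:
    """Per-condition trial-average waveforms for one subject/session."""

    data: dict[str, np.ndarray]       # condition -> (channels, samples), uV
    n_retained: dict[str, int]
    excluded: set[str]                # conditions failing the min-trial rule
    times: np.ndarray
    ch_names: tuple[str, ...]
    sample_rate: float
    subject_id: str = ""
    group: str = ""
    age_months: int = 0

    def available(self, *conditions: str) -> bool:
        return all(c in self.data and c not in self.excluded for c in conditions)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def bandpass_sos(band: tuple[float, float], sample_rate: float, order: int = 4):
    lo, hi = band
    if hi >= sample_rate / 2:
        raise ValueError("high corner must be below Nyquist")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")


def bandpass(
    data: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = (0.1, 30.0),
    order: int = 4,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along the last axis."""
    sos = bandpass_sos(band, sample_rate, order)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if data.shape[-1] <= padlen:
        raise ValueError(
            f"recording of {data.shape[-1]} samples is shorter than the "
            f"filter warm-up ({padlen} samples)"
        )
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass_recording(rec: SimulatedRecording, cfg: PreprocConfig) -> SimulatedRecording:
    filtered = bandpass(rec.data, rec.sample_rate, cfg.band, cfg.filter_order)
    return SimulatedRecording(
        data=filtered,
        ch_names=rec.ch_names,
        sample_rate=rec.sample_rate,
        events=rec.events,
        subject_id=rec.subject_id,
        group=rec.group,
        age_months=rec.age_months,
        seed=rec.seed,
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def window_samples(window: tuple[float, float], sample_rate: float) -> tuple[int, int]:
    """Sample offsets for an epoch window, inclusive at both ends."""
    lo = int(round(window[0] * sample_rate / 1000.0))
    hi = int(round(window[1] * sample_rate / 1000.0))
    return lo, hi


def segment(rec: SimulatedRecording, cfg: PreprocConfig) -> EpochSet:
    """Cut one epoch per event; events too near an edge are flagged, not fatal.

    Epochs use inclusive endpoints: at 500 Hz a -100..800 ms window is
    451 samples with sample 50 at stimulus onset.  Adjacent epochs may
    overlap (the 550 ms onset asynchrony is shorter than the epoch).
    """
    lo, hi = window_samples(cfg.epoch_window, rec.sample_rate)
    n_samp = hi - lo + 1
    times = (np.arange(lo, hi + 1)) * 1000.0 / rec.sample_rate

    epochs: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    keep: dict[str, list[bool]] = {c: [] for c in CONDITIONS}
    reasons: dict[str, list[str | None]] = {c: [] for c in CONDITIONS}
    presented: dict[str, int] = {c: 0 for c in CONDITIONS}

    for onset, label in zip(rec.events["onset_sample"], rec.events["label"]):
        if label not in epochs:
            continue
        presented[label] += 1
        start, stop = onset + lo, onset + hi + 1
        if start < 0 or stop > rec.n_samples:
            epochs[label].append(np.zeros((len(rec.ch_names), n_samp)))
            keep[label].append(False)
            reasons[label].append(REASON_EDGE)
            continue
        epochs[label].append(rec.data[:, start:stop].copy())
        keep[label].append(True)
        reasons[label].append(None)

    out_epochs = {
        c: (np.stack(v) if v else np.empty((0, len(rec.ch_names), n_samp)))
        for c, v in epochs.items()
    }
    return EpochSet(
        epochs=out_epochs,
        keep={c: np.array(v, dtype=bool) for c, v in keep.items()},
        reject_reason=reasons,
        bad_channels={c: [[] for _ in v] for c, v in keep.items()},
        times=times,
        ch_names=rec.ch_names,
        sample_rate=rec.sample_rate,
        n_presented=presented,
    )


# ---------------------------------------------------------------------------
# artifact handling
# ---------------------------------------------------------------------------

def detect_artifacts(epochs: EpochSet, cfg: PreprocConfig) -> EpochSet:
    """Flag channels whose peak-to-peak amplitude exceeds the threshold.

    An epoch is rejected outright when strictly more than
    ``bad_channel_limit`` channels are bad (before interpolation);
    otherwise its bad channels are queued for interpolation.
    """
    for cond, tensor in epochs.epochs.items():
        for t in range(tensor.shape[0]):
            if not epochs.keep[cond][t]:
                continue
            ptp = tensor[t].max(axis=1) - tensor[t].min(axis=1)
            bad = np.flatnonzero(ptp > cfg.ptp_threshold)
            if bad.size > cfg.bad_channel_limit:
                epochs.keep[cond][t] = False
                epochs.reject_reason[cond][t] = REASON_TOO_MANY_BAD
                epochs.bad_channels[cond][t] = bad.tolist()
            else:
                epochs.bad_channels[cond][t] = bad.tolist()
    return epochs


def _idw_weights(
    positions: np.ndarray, bad: np.ndarray, good: np.ndarray, power: float = 2.0
) -> np.ndarray:
    """Inverse-distance weights (rows: bad channels, columns: good)."""
    d = np.linalg.norm(positions[bad][:, None, :] - positions[good][None, :, :], axis=2)
    w = 1.0 / np.maximum(d, 1e-6) ** power
    return w / w.sum(axis=1, keepdims=True)


def interpolate_bad_channels(
    epochs: EpochSet, montage: Montage, cfg: PreprocConfig
) -> EpochSet:
    """Replace flagged channels by IDW neighbour averages; reject if impossible."""
    positions = montage.position_array()
    n_ch = len(epochs.ch_names)
    for cond, tensor in epochs.epochs.items():
        for t in range(tensor.shape[0]):
            if not epochs.keep[cond][t]:
                continue
            bad = np.asarray(epochs.bad_channels[cond][t], dtype=int)
            if bad.size == 0:
                continue
            good = np.setdiff1d(np.arange(n_ch), bad)
            if good.size < cfg.min_good_neighbours:
                epochs.keep[cond][t] = False
                epochs.reject_reason[cond][t] = REASON_UNINTERPOLABLE
                continue
            w = _idw_weights(positions, bad, good)
            tensor[t, bad, :] = w @ tensor[t, good, :]
    return epochs


# ---------------------------------------------------------------------------
# baseline + reference
# ---------------------------------------------------------------------------

def baseline_and_rereference(epochs: EpochSet, cfg: PreprocConfig) -> EpochSet:
    """Subtract the pre-stimulus baseline mean per channel, then the
    across-channel mean per sample (average reference).

    Idempotent: both means are zero afterwards, so re-running is a no-op.
    """
    mask = (epochs.times >= cfg.baseline_window[0]) & (
        epochs.times <= cfg.baseline_window[1]
    )
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    for cond, tensor in epochs.epochs.items():
        if tensor.size == 0:
            continue
        tensor -= tensor[:, :, mask].mean(axis=2, keepdims=True)
        tensor -= tensor.mean(axis=1, keepdims=True)
    return epochs


# ---------------------------------------------------------------------------
# truncation and averaging
# ---------------------------------------------------------------------------

def truncate_and_average(
    epochs: EpochSet,
    cfg: PreprocConfig,
    subject_id: str = "",
    group: str = "",
    age_months: int = 0,
) -> ConditionERP:
    """Average the first N retained trials per condition.

    N is 120 for standards and 65 for deviants (longer paradigm versions
    are truncated so exposure is comparable).  Conditions retaining
    fewer than ``min_trials`` trials are marked excluded for this
    subject; the subject remains usable for other conditions.
    """
    data: dict[str, np.ndarray] = {}
    n_retained: dict[str, int] = {}
    excluded: set[str] = set()
    for cond, tensor in epochs.epochs.items():
        cap = cfg.cap_for(cond)
        idx = np.flatnonzero(epochs.keep[cond])[:cap]
        # trials beyond the cap recorded as over-cap, not artifact rejections
        for extra in np.flatnonzero(epochs.keep[cond])[cap:]:
            epochs.reject_reason[cond][extra] = REASON_OVER_CAP
        n_retained[cond] = idx.size
        if idx.size < cfg.min_trials:
            excluded.add(cond)
            continue
        data[cond] = tensor[idx].mean(axis=0)
    return ConditionERP(
        data=data,
        n_retained=n_retained,
        excluded=excluded,
        times=epochs.times,
        ch_names=epochs.ch_names,
        sample_rate=epochs.sample_rate,
        subject_id=subject_id,
        group=group,
        age_months=age_months,
    )


def preprocess_recording(
    rec: SimulatedRecording,
    montage: Montage,
    cfg: PreprocConfig | None = None,
) -> ConditionERP:
    """Full preprocessing chain for one recording."""
    cfg = cfg or PreprocConfig()
    filtered = bandpass_recording(rec, cfg)
    epochs = segment(filtered, cfg)
    epochs = detect_artifacts(epochs, cfg)
    epochs = interpolate_bad_channels(epochs, montage, cfg)
    epochs = baseline_and_rereference(epochs, cfg)
    return truncate_and_average(
        epochs, cfg, rec.subject_id, rec.group, rec.age_months
    )
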