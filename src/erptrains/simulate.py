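"""Synthetic trains-of-vowels EEG cohorts with plantable effects.

The paradigm: trains of four 50-ms sounds — three repeated standard
vowels (S1, S2, S3) followed by a deviant that changes either pitch or
vowel category (50/50) — with a jittered ~500 ms inter-stimulus interval
within trains and a random 3–4 s inter-train interval, recorded as
multi-channel EEG at 500 Hz.

Stimulus audio is never synthesised; conditions are symbolic labels.
Each condition evokes region-specific ERP deflections modelled as
raised-cosine bumps, with opposite polarity over frontal and posterior
scalp.  Noise is band-limited (0.1-30 Hz by default), which reproduces
the very high lag-1 autocorrelation (~0.98) of real ERP difference
waveforms.  Group (TD / NF1) and age (5 / 10 months) scale amplitudes
and shift onsets; a per-subject latent responsiveness factor couples
neural effect sizes to simulated developmental-outcome scores so that
correlation-recovery can be tested end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import Montage, REGIONS, default_montage

CONDITIONS = ("S1", "S2", "S3", "DevPitch", "DevVowel")
STANDARDS = ("S1", "S2", "S3")
DEVIANTS = ("DevPitch", "DevVowel")
GROUPS = ("TD", "NF1")
AGES_MONTHS = (5, 10)


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParadigmConfig:
    """Timing of the trains-of-sounds paradigm.

    All durations in milliseconds; ``sample_rate`` in Hz.  The ISI is
    drawn uniformly in ``isi_mean +/- isi_jitter_halfwidth`` and measured
    offset-to-onset, so onset asynchrony within a train is
    ``stim_duration + ISI``.  The inter-train interval (offset of the
    deviant to onset of the next S1) is uniform in ``iti_range``.
    """

    sample_rate: float = 500.0
    stim_duration: float = 50.0
    isi_mean: float = 500.0
    isi_jitter_halfwidth: float = 100.0
    iti_range: tuple[float, float] = (3000.0, 4000.0)
    n_trains: int = 120
    deviant_pitch_prob: float = 0.5
    session_cap_minutes: float = 10.0
    lead_in: float = 1000.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_trains <= 0:
            raise ValueError("n_trains must be positive")
        if self.iti_range[0] > self.iti_range[1]:
            raise ValueError("iti_range low must not exceed high")
        if not 0.0 <= self.deviant_pitch_prob <= 1.0:
            raise ValueError("deviant_pitch_prob must be a probability")
        if self.isi_jitter_halfwidth < 0 or self.isi_jitter_halfwidth > self.isi_mean:
            raise ValueError("isi jitter must be within [0, isi_mean]")


@dataclass(frozen=True)
class Bump:
    """Half-period raised-cosine deflection: a*sin^2(pi (t-onset)/width)."""

    amplitude: float  # uV, signed
    onset: float      # ms post stimulus onset
    width: float      # ms; peak at onset + width/2

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bump width must be positive")
        if self.onset < 0:
            raise ValueError("bump onset must be non-negative")

    @property
    def peak_latency(self) -> float:
        return self.onset + self.width / 2.0

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        u = (times_ms - self.onset) / self.width
        out = np.zeros_like(times_ms, dtype=float)
        mask = (u >= 0.0) & (u <= 1.0)
        out[mask] = self.amplitude * np.sin(np.pi * u[mask]) ** 2
        return out


@dataclass(frozen=True)
class Modifier:
    """Group/age modulation of evoked templates."""

    amp_scale: float = 1.0
    onset_shift: float = 0.0  # ms


@dataclass(frozen=True)
class EffectSpec:
    """Evoked templates per condition and region, with group/age modifiers.

    ``templates[condition][region]`` is a tuple of :class:`Bump`.  Frontal
    and posterior bumps conventionally carry opposite polarity so the
    across-channel (average-reference) mean stays near zero.
    """

    templates: dict[str, dict[str, tuple[Bump, ...]]]
    group_modifiers: dict[str, Modifier] = field(
        default_factory=lambda: {"TD": Modifier(), "NF1": Modifier()}
    )
    age_modifiers: dict[int, Modifier] = field(
        default_factory=lambda: {5: Modifier(), 10: Modifier()}
    )

    def modifier(self, group: str, age_months: int) -> Modifier:
        g = self.group_modifiers.get(group, Modifier())
        a = self.age_modifiers.get(age_months, Modifier())
        return Modifier(g.amp_scale * a.amp_scale, g.onset_shift + a.onset_shift)

    def condition_waveform(
        self,
        condition: str,
        region: str,
        times_ms: np.ndarray,
        group: str = "TD",
        age_months: int = 5,
        amp_scale: float = 1.0,
        max_latency: float | None = None,
    ) -> np.ndarray:
        mod = self.modifier(group, age_months)
        out = np.zeros_like(times_ms, dtype=float)
        for bump in self.templates.get(condition, {}).get(region, ()):
            shifted = replace(bump, onset=bump.onset + mod.onset_shift)
            if max_latency is not None and shifted.onset + shifted.width > max_latency:
                raise ValueError(
                    f"effect for {condition}/{region} extends to "
                    f"{shifted.onset + shifted.width:.0f} ms, beyond the "
                    f"{max_latency:.0f} ms epoch span"
                )
            out += mod.amp_scale * amp_scale * shifted.waveform(times_ms)
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Background EEG noise and artifact model.

    ``spectrum`` selects the spectral shape: ``"bandlimited"`` is white
    within ``band`` and zero outside (FFT brick-wall), ``"pink"`` weights
    the in-band spectrum by 1/f, ``"white"`` is unfiltered.  Band-limited
    noise at 0.1-30 Hz / 500 Hz has lag-1 autocorrelation close to the
    ideal sinc value sin(2*pi*B*tau)/(2*pi*B*tau) ~ 0.976.

    Artifacts mix blink-like low-frequency frontal transients and
    motion-like broadband bursts, both at ``artifact_rate`` per minute.
    """

    std: float = 20.0  # uV marginal standard deviation
    band: tuple[float, float] = (0.1, 30.0)
    spectrum: str = "bandlimited"
    subject_scale_sigma: float = 0.2  # lognormal sigma of per-subject scaling
    artifact_rate: float = 3.0       # per minute
    artifact_amplitude: float = 150.0  # uV
    artifact_duration: float = 400.0   # ms

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("noise std must be non-negative")
        if self.spectrum not in ("bandlimited", "pink", "white"):
            raise ValueError(f"unknown spectrum {self.spectrum!r}")


@dataclass
class SimulatedRecording:
    """Continuous multi-channel EEG plus its event table for one session."""

    data: np.ndarray               # (n_channels, n_samples), uV
    ch_names: tuple[str, ...]
    sample_rate: float
    events: pd.DataFrame           # onset_sample, onset_ms, label, train_index
    subject_id: str
    group: str
    age_months: int
    seed: int

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------

def generate_event_sequence(
    cfg: ParadigmConfig, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw one session's stimulus schedule.

    Each train contributes events S1, S2, S3 then a deviant whose label
    is DevPitch with probability ``deviant_pitch_prob`` else DevVowel.
    The schedule stops early (whole trains only) once the session cap
    would be exceeded.
    """
    rng = np.random.default_rng(seed)
    cap_ms = cfg.session_cap_minutes * 60_000.0
    rows: list[tuple[int, float, str, int]] = []
    t = cfg.lead_in
    for train in range(cfg.n_trains):
        jitter = cfg.isi_jitter_halfwidth
        isis = rng.uniform(cfg.isi_mean - jitter, cfg.isi_mean + jitter, size=3)
        onsets = [t]
        for isi in isis:
            onsets.append(onsets[-1] + cfg.stim_duration + isi)
        if onsets[-1] + cfg.stim_duration > cap_ms:
            break
        deviant = "DevPitch" if rng.random() < cfg.deviant_pitch_prob else "DevVowel"
        labels = ["S1", "S2", "S3", deviant]
        for onset, label in zip(onsets, labels):
            rows.append(
                (int(round(onset * cfg.sample_rate / 1000.0)), onset, label, train)
            )
        t = onsets[-1] + cfg.stim_duration + rng.uniform(*cfg.iti_range)
    events = pd.DataFrame(
        rows, columns=["onset_sample", "onset_ms", "label", "train_index"]
    )
    return events


# ---------------------------------------------------------------------------
# noise and artifacts
# ---------------------------------------------------------------------------

def bandlimited_noise(
    n_channels: int,
    n_samples: int,
    spec: NoiseSpec,
    sample_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary noise with the requested spectral shape, unit variance."""
    white = rng.standard_normal((n_channels, n_samples))
    if spec.spectrum == "white":
        return white
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    spectrum = np.fft.rfft(white, axis=1)
    lo, hi = spec.band
    keep = (freqs >= lo) & (freqs <= hi)
    weight = keep.astype(float)
    if spec.spectrum == "pink":
        with np.errstate(divide="ignore"):
            weight = np.where(keep, 1.0 / np.sqrt(np.maximum(freqs, lo)), 0.0)
    spectrum *= weight
    out = np.fft.irfft(spectrum, n=n_samples, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def inject_artifacts(
    data: np.ndarray,
    montage: Montage,
    spec: NoiseSpec,
    sample_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add blink-like frontal transients and broadband motion bursts in place."""
    n_channels, n_samples = data.shape
    minutes = n_samples / sample_rate / 60.0
    n_artifacts = rng.poisson(spec.artifact_rate * minutes)
    if n_artifacts == 0:
        return data
    dur = max(2, int(round(spec.artifact_duration * sample_rate / 1000.0)))
    pos = montage.position_array()
    # frontal weighting for blinks: strongest at the most anterior channels
    anterior = np.clip(pos[:, 1], 0.0, None)
    anterior = anterior / anterior.max() if anterior.max() > 0 else anterior
    shape = np.sin(np.pi * np.arange(dur) / (dur - 1)) ** 2
    for _ in range(n_artifacts):
        start = rng.integers(0, max(1, n_samples - dur))
        if rng.random() < 0.5:  # blink-like
            amp = spec.artifact_amplitude * rng.uniform(0.8, 1.5)
            data[:, start : start + dur] += amp * anterior[:, None] * shape[None, :]
        else:  # motion-like broadband burst on all channels
            burst = rng.standard_normal((n_channels, dur))
            data[:, start : start + dur] += (
                spec.artifact_amplitude * 0.5 * burst * shape[None, :]
            )
    return data


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

EPOCH_SPAN_MS = 800.0  # evoked templates must fit the post-onset epoch span


def generate_subject_recording(
    cfg: ParadigmConfig,
    effects: EffectSpec,
    noise: NoiseSpec,
    montage: Montage | None = None,
    subject_id: str = "sub-01",
    group: str = "TD",
    age_months: int = 5,
    seed: int | np.random.Generator = 0,
    amp_scale: float = 1.0,
    noise_scale: float = 1.0,
) -> SimulatedRecording:
    """Synthesise one continuous recording: templates + noise + artifacts."""
    montage = montage or default_montage()
    montage.validate_cells()
    rng = np.random.default_rng(seed)
    seed_val = int(rng.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed_val)

    events = generate_event_sequence(cfg, rng)
    if events.empty:
        raise ValueError("paradigm produced no events (cap too tight?)")
    last = float(events["onset_ms"].iloc[-1])
    n_samples = int(round((last + EPOCH_SPAN_MS + cfg.lead_in) * cfg.sample_rate / 1000.0))
    data = np.zeros((montage.n_channels, n_samples))

    # evoked templates, one per region; channels share their region's waveform
    tmpl_len = int(round(EPOCH_SPAN_MS * cfg.sample_rate / 1000.0)) + 1
    tmpl_times = np.arange(tmpl_len) * 1000.0 / cfg.sample_rate
    region_templates = {
        region: {
            cond: effects.condition_waveform(
                cond, region, tmpl_times, group, age_months, amp_scale,
                max_latency=EPOCH_SPAN_MS,
            )
            for cond in CONDITIONS
        }
        for region in REGIONS
    }
    region_of = {ch: rs[0] for ch, rs in montage.region_map.items()}
    for onset_sample, label in zip(events["onset_sample"], events["label"]):
        stop = min(onset_sample + tmpl_len, n_samples)
        for i, ch in enumerate(montage.ch_names):
            region = region_of.get(ch)
            if region is None:
                continue
            data[i, onset_sample:stop] += region_templates[region][label][: stop - onset_sample]

    if noise.std > 0:
        data += (
            noise.std
            * noise_scale
            * bandlimited_noise(montage.n_channels, n_samples, noise, cfg.sample_rate, rng)
        )
        inject_artifacts(data, montage, noise, cfg.sample_rate, rng)

    return SimulatedRecording(
        data=data,
        ch_names=montage.ch_names,
        sample_rate=cfg.sample_rate,
        events=events,
        subject_id=subject_id,
        group=group,
        age_months=age_months,
        seed=seed_val,
    )


# ---------------------------------------------------------------------------
# cohort and outcome scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Cell sizes per group; subjects are followed at every age point."""

    n_td: int = 10
    n_nf1: int = 10
    ages: tuple[int, ...] = AGES_MONTHS
    outcome_neural_r: float = 0.4

    def __post_init__(self) -> None:
        if self.n_td < 0 or self.n_nf1 < 0:
            raise ValueError("cell sizes must be non-negative")
        if not -1.0 <= self.outcome_neural_r <= 1.0:
            raise ValueError("outcome_neural_r must be a correlation")


# invented instrument-like score distributions (mean, sd, low clip) at 14 m
_OUTCOME_SCALES = {
    "msel_receptive_raw": (30.0, 5.0, 0.0),
    "msel_expressive_raw": (26.0, 5.0, 0.0),
    "cdi_words_understood": (120.0, 60.0, 0.0),
    "cdi_words_understands_says": (40.0, 25.0, 0.0),
    "ibqr_activity": (4.0, 0.8, 1.0),
    "aosi_total": (8.0, 4.0, 0.0),
}
# NF1 mean shifts in the same units (language lower, ASD traits higher)
_NF1_SHIFT = {
    "msel_receptive_raw": -3.0,
    "msel_expressive_raw": -3.0,
    "cdi_words_understood": -25.0,
    "cdi_words_understands_says": -10.0,
    "ibqr_activity": 0.3,
    "aosi_total": 0.0,
}


def generate_outcomes(
    subjects: pd.DataFrame,
    latent: np.ndarray,
    rho: float,
    rng: np.random.Generator,
    ibqr_missing_prob: float = 0.1,
) -> pd.DataFrame:
    """Outcome scores correlated (Pearson rho) with the latent neural factor.

    ``subjects`` needs columns subject and group.  AOSI is administered
    to the NF1 group only; IBQ-R item missingness occasionally exceeds
    the 20% blanking rule applied downstream.
    """
    n = len(subjects)
    out = {"subject": subjects["subject"].to_numpy(), "group": subjects["group"].to_numpy()}
    nf1 = out["group"] == "NF1"
    for score, (mean, sd, low) in _OUTCOME_SCALES.items():
        eps = rng.standard_normal(n)
        z = rho * latent + math.sqrt(max(0.0, 1.0 - rho**2)) * eps
        vals = mean + _NF1_SHIFT[score] * nf1 + sd * z
        vals = np.clip(vals, low, None)
        if score == "aosi_total":
            vals = np.where(nf1, vals, np.nan)
        out[score] = vals
    out["ibqr_missing_frac"] = np.where(
        rng.random(n) < ibqr_missing_prob, rng.uniform(0.2, 0.5, n), 0.0
    )
    return pd.DataFrame(out)


def generate_cohort(
    design: CohortDesign,
    cfg: ParadigmConfig | None = None,
    effects: "EffectSpec | None" = None,
    noise: NoiseSpec | None = None,
    montage: Montage | None = None,
    seed: int = 0,
) -> tuple[list[SimulatedRecording], pd.DataFrame]:
    """Simulate a longitudinal cohort: recordings per subject x age + outcomes.

    A master seed spawns one independent substream per subject session
    (and one for outcomes), so any subject's data can be regenerated
    without simulating the rest of the cohort.
    """
    cfg = cfg or ParadigmConfig()
    effects = effects or default_effects()
    noise = noise or default_noise()
    montage = montage or default_montage()

    subjects = [("TD", i) for i in range(design.n_td)] + [
        ("NF1", i) for i in range(design.n_nf1)
    ]
    n_sub = len(subjects)
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n_sub * len(design.ages) + 2)
    meta_rng = np.random.default_rng(streams[-2])
    latent = meta_rng.standard_normal(n_sub)
    amp_scales = np.clip(1.0 + 0.25 * latent, 0.1, None)
    noise_scales = np.exp(noise.subject_scale_sigma * meta_rng.standard_normal(n_sub))

    recordings: list[SimulatedRecording] = []
    k = 0
    sub_rows = []
    for s_idx, (grp, i) in enumerate(subjects):
        sid = f"sub-{grp}{i:03d}"
        sub_rows.append((sid, grp))
        for age in design.ages:
            recordings.append(
                generate_subject_recording(
                    cfg, effects, noise, montage,
                    subject_id=sid, group=grp, age_months=age,
                    seed=np.random.default_rng(streams[k]),
                    amp_scale=float(amp_scales[s_idx]),
                    noise_scale=float(noise_scales[s_idx]),
                )
            )
            k += 1
    sub_df = pd.DataFrame(sub_rows, columns=["subject", "group"])
    outcomes = generate_outcomes(
        sub_df, latent, design.outcome_neural_r, np.random.default_rng(streams[-1])
    )
    outcomes["latent_neural"] = latent
    return recordings, outcomes


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def default_effects() -> EffectSpec:
    """Evoked templates emulating the study's observed response pattern.

    Frontal responses are negative-going and posterior responses mirror
    them (opposite polarity), so the 12-channel average reference leaves
    the templates unchanged.  Magnitudes follow the reported marginal
    means: first-standard frontal response ~ -4 uV, repetition
    suppression (S1-S2) ~ -5 uV frontal / +5 uV posterior, deviance
    (S2-Dev) ~ -5 uV frontal / +5 uV posterior, and a small late
    pitch-vs-vowel difference.  All bumps end by 440 ms post onset so
    the next stimulus' baseline stays clean at the shortest asynchrony.
    """
    def pair(frontal_bumps: tuple[Bump, ...]) -> dict[str, tuple[Bump, ...]]:
        posterior = tuple(
            Bump(-b.amplitude, b.onset, b.width) for b in frontal_bumps
        )
        return {"frontal": frontal_bumps, "posterior": posterior}

    templates = {
        "S1": pair((Bump(-4.0, 80.0, 340.0),)),
        "S2": pair((Bump(1.0, 80.0, 340.0),)),
        "S3": pair((Bump(1.5, 80.0, 340.0),)),
        "DevPitch": pair((Bump(6.0, 80.0, 340.0),)),
        "DevVowel": pair((Bump(6.0, 80.0, 340.0), Bump(-1.2, 300.0, 140.0))),
    }
    return EffectSpec(
        templates=templates,
        group_modifiers={"TD": Modifier(), "NF1": Modifier(amp_scale=0.75)},
        age_modifiers={5: Modifier(), 10: Modifier(amp_scale=0.8)},
    )


def default_noise() -> NoiseSpec:
    return NoiseSpec()


# ---------------------------------------------------------------------------
# synthetic factor-structure data for the component-analysis stage
# ---------------------------------------------------------------------------

FACTOR_VARIABLES = tuple(
    f"{c}_{r}" for c in ("S1", "S1-S2", "S2-DevPitch", "S2-DevVowel")
    for r in ("frontal", "posterior")
)

# two-component pattern emulating the reported solution: the deviant
# contrasts load on one (oblique) component and S1 / S1-S2 on the other,
# frontal variables positive and posterior negative
DEFAULT_LOADING_PATTERN = {
    "S1_frontal": (0.0, 0.90),
    "S1_posterior": (0.0, -0.56),
    "S1-S2_frontal": (0.0, 0.85),
    "S1-S2_posterior": (0.0, -0.70),
    "S2-DevPitch_frontal": (0.80, 0.0),
    "S2-DevPitch_posterior": (-0.78, 0.0),
    "S2-DevVowel_frontal": (0.82, 0.0),
    "S2-DevVowel_posterior": (-0.76, 0.0),
}


def generate_factor_structure_data(
    n_subjects: int,
    seed: int | np.random.Generator = 0,
    loadings: dict[str, tuple[float, float]] | None = None,
    component_corr: float = 0.3,
) -> pd.DataFrame:
    """Draw the eight mean-amplitude variables from a planted two-component
    model: X = F L' + E with correlated components and unit total variance
    per variable (uniqueness = 1 - communality)."""
    rng = np.random.default_rng(seed)
    loadings = loadings or DEFAULT_LOADING_PATTERN
    L = np.array([loadings[v] for v in FACTOR_VARIABLES])
    phi = np.array([[1.0, component_corr], [component_corr, 1.0]])
    communal = np.einsum("ij,jk,ik->i", L, phi, L)
    if np.any(communal >= 1.0):
        raise ValueError("planted communalities must stay below 1")
    chol = np.linalg.cholesky(phi)
    F = rng.standard_normal((n_subjects, 2)) @ chol.T
    E = rng.standard_normal((n_subjects, len(FACTOR_VARIABLES)))
    X = F @ L.T + E * np.sqrt(1.0 - communal)
    df = pd.DataFrame(X, columns=list(FACTOR_VARIABLES))
    df.insert(0, "subject", [f"sub-{i:03d}" for i in range(n_subjects)])
    df.insert(1, "group", "TD")
    df.insert(2, "age", 10)
    return df
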