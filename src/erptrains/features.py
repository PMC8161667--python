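"""Contrast waveforms and windowed mean-amplitude features.

Condition-average ERPs are collapsed over the channels of each scalp
cell, differenced into the analysis contrasts (S1 passes through as the
overall first-standard response), restricted to the first 500 ms post
onset (250 points on the native 2-ms grid), and summarised as mean
amplitudes over eight 50-ms windows from 100 to 500 ms.  Windows are
half-open [a, b) so they tile 100-500 ms without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import Montage, REGIONS, SITES
from .preprocess import ConditionERP

# analysis contrasts: name -> (minuend, subtrahend); None = pass-through
CONTRASTS: dict[str, tuple[str, str | None]] = {
    "S1": ("S1", None),
    "S1-S2": ("S1", "S2"),
    "S2-S3": ("S2", "S3"),
    "S2-DevPitch": ("S2", "DevPitch"),
    "S2-DevVowel": ("S2", "DevVowel"),
    "DevPitch-DevVowel": ("DevPitch", "DevVowel"),
}

FACTOR_CONTRASTS = ("S1", "S1-S2", "S2-DevPitch", "S2-DevVowel")

ANALYSIS_SPAN_MS = (0.0, 500.0)
WINDOWS_MS: tuple[tuple[float, float], ...] = tuple(
    (float(a), float(a + 50)) for a in range(100, 500, 50)
)
SITE_COLLAPSED = "all"


def window_label(window: tuple[float, float]) -> str:
    return f"{int(window[0])}-{int(window[1])}"


@dataclass
class ContrastWaveformSet:
    """Long-format contrast waveforms on the 0-500 ms analysis grid.

    ``index`` rows (subject, group, age, region, site, contrast) align
    with rows of ``waveforms``; ``site`` is a site label or ``"all"``
    for the site-collapsed (all-channel) average.
    """

    index: pd.DataFrame
    waveforms: np.ndarray  # (n_rows, n_times), uV
    times: np.ndarray      # ms, half-open [0, 500)

    def select(
        self,
        contrast: str,
        region: str,
        site: str = SITE_COLLAPSED,
        group: str | None = None,
        age: int | None = None,
    ) -> tuple[pd.DataFrame, np.ndarray]:
        m = (
            (self.index["contrast"] == contrast)
            & (self.index["region"] == region)
            & (self.index["site"] == site)
        )
        if group is not None:
            m &= self.index["group"] == group
        if age is not None:
            m &= self.index["age"] == age
        return self.index[m].reset_index(drop=True), self.waveforms[m.to_numpy()]


def regional_waveform(
    erp: ConditionERP,
    montage: Montage,
    condition: str,
    region: str,
    site: str | None = None,
) -> np.ndarray:
    """Unweighted mean waveform across the channels of one scalp cell.

    ``site=None`` collapses across left/central/right (all channels of
    the region), which equals the channel-count-weighted mean of the
    three site waveforms.
    """
    members = montage.cell_channels(region, site)
    if not members:
        raise ValueError(f"empty montage cell: {region}/{site}")
    idx = [erp.ch_names.index(ch) for ch in members]
    return erp.data[condition][idx].mean(axis=0)


def analysis_grid(erp_times: np.ndarray) -> np.ndarray:
    lo, hi = ANALYSIS_SPAN_MS
    return (erp_times >= lo) & (erp_times < hi)


def build_contrasts(
    erps: list[ConditionERP],
    montage: Montage,
    contrasts: dict[str, tuple[str, str | None]] | None = None,
) -> ContrastWaveformSet:
    """Assemble contrast waveforms for every subject/session.

    A contrast is produced only when every constituent condition
    survived the minimum-trial rule; otherwise it is simply absent for
    that subject (recorded by omission, consumed downstream as missing).
    """
    contrasts = contrasts or CONTRASTS
    rows: list[tuple] = []
    waves: list[np.ndarray] = []
    times_out: np.ndarray | None = None
    for erp in erps:
        mask = analysis_grid(erp.times)
        if times_out is None:
            times_out = erp.times[mask]
        for name, (a, b) in contrasts.items():
            needed = (a,) if b is None else (a, b)
            if not erp.available(*needed):
                continue
            for region in REGIONS:
                for site in (SITE_COLLAPSED, *SITES):
                    s = None if site == SITE_COLLAPSED else site
                    wa = regional_waveform(erp, montage, a, region, s)
                    w = wa if b is None else wa - regional_waveform(erp, montage, b, region, s)
                    rows.append(
                        (erp.subject_id, erp.group, erp.age_months, region, site, name)
                    )
                    waves.append(w[mask])
    index = pd.DataFrame(
        rows, columns=["subject", "group", "age", "region", "site", "contrast"]
    )
    if times_out is None:
        raise ValueError("no ERPs supplied")
    waveforms = np.stack(waves) if waves else np.empty((0, times_out.size))
    return ContrastWaveformSet(index=index, waveforms=waveforms, times=times_out)


def windowed_means(cset: ContrastWaveformSet) -> pd.DataFrame:
    """Mean amplitude per 50-ms window (half-open [a, b)), long format.

    One row per subject x region x site x contrast x window; the
    site-collapsed rows are excluded (the windowed models use site as a
    factor).  Window means are re-derivable bit-identically from the
    contrast waveforms.
    """
    recs = []
    site_rows = cset.index["site"] != SITE_COLLAPSED
    idx = cset.index[site_rows].reset_index(drop=True)
    waves = cset.waveforms[site_rows.to_numpy()]
    for window in WINDOWS_MS:
        m = (cset.times >= window[0]) & (cset.times < window[1])
        means = waves[:, m].mean(axis=1)
        for row, val in zip(idx.itertuples(index=False), means):
            recs.append((*row, window_label(window), val))
    return pd.DataFrame(
        recs,
        columns=[
            "subject", "group", "age", "region", "site", "contrast",
            "window", "amplitude",
        ],
    )


def factor_input_means(cset: ContrastWaveformSet) -> pd.DataFrame:
    """The eight variables entering the component analysis.

    Per subject x age: site-collapsed 100-500 ms mean amplitude of the
    S1, S1-S2, S2-DevPitch and S2-DevVowel contrasts, frontal and
    posterior separately.  Missing contrasts yield missing values; the
    subject row is retained.
    """
    m = (cset.times >= 100.0) & (cset.times < 500.0)
    rows: dict[tuple, dict] = {}
    for i, row in enumerate(cset.index.itertuples(index=False)):
        if row.site != SITE_COLLAPSED or row.contrast not in FACTOR_CONTRASTS:
            continue
        key = (row.subject, row.age)
        rec = rows.setdefault(
            key, {"subject": row.subject, "group": row.group, "age": row.age}
        )
        rec[f"{row.contrast}_{row.region}"] = cset.waveforms[i, m].mean()
    cols = ["subject", "group", "age"] + [
        f"{c}_{r}" for c in FACTOR_CONTRASTS for r in REGIONS
    ]
    df = pd.DataFrame(list(rows.values()))
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols].sort_values(["subject", "age"]).reset_index(drop=True)


def factor_variable_names() -> list[str]:
    return [f"{c}_{r}" for c in FACTOR_CONTRASTS for r in REGIONS]
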