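"""End-to-end orchestration: simulate -> preprocess -> features ->
run-length test -> cohort statistics.

A single YAML config drives every stage; outputs are UTF-8 CSV/TSV
tables plus a JSON run manifest (config snapshot, seeds, per-stage
paths, retention summary).  Re-running with the same config and seed
reproduces all outputs; when the feature tables already exist a run can
resume from them, skipping simulation and preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as eio
from .features import (
    CONTRASTS,
    SITE_COLLAPSED,
    ContrastWaveformSet,
    build_contrasts,
    factor_input_means,
    factor_variable_names,
    windowed_means,
)
from .montage import Montage, REGIONS, default_montage, dense_montage
from .preprocess import PreprocConfig, preprocess_recording
from .runtest import RunTestConfig, detect_intervals, estimate_lag1, pointwise_paired_t, simulate_null
from .simulate import (
    AGES_MONTHS,
    CohortDesign,
    EffectSpec,
    NoiseSpec,
    ParadigmConfig,
    default_effects,
    generate_cohort,
)
from .stats import (
    ModelSpec,
    correlate_outcomes,
    fit_window_lmm,
    pairwise_followup,
    partial_correlate,
    pca_oblimin,
    score_composites,
)

__version__ = "0.1.0"
log = logging.getLogger("erptrains")

RUNTEST_CONTRASTS = ("S1-S2", "S2-DevPitch", "S2-DevVowel", "DevPitch-DevVowel")
LMM_CONTRASTS = ("S1", "S1-S2", "S2-DevPitch", "S2-DevVowel")


def _montage_from_config(cfg: dict) -> Montage:
    name = cfg.get("montage", "default")
    if name == "default":
        return default_montage()
    if name == "dense":
        return dense_montage()
    raise ValueError(f"unknown montage {name!r}")


def setup_logging(out_dir: Path, level: str = "INFO") -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    handlers = [logging.StreamHandler(), logging.FileHandler(out_dir / "run.log")]
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, out: Path, seed: int):
    paradigm = ParadigmConfig(**cfg.get("paradigm", {}))
    noise = NoiseSpec(**cfg.get("noise", {}))
    design = CohortDesign(**cfg.get("design", {}))
    effects = default_effects()
    montage = _montage_from_config(cfg)
    log.info(
        "simulate: %d TD + %d NF1 subjects, ages %s, seed %d",
        design.n_td, design.n_nf1, design.ages, seed,
    )
    recordings, outcomes = generate_cohort(design, paradigm, effects, noise, montage, seed)
    ev_dir = out / "events"
    ev_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        eio.write_events_tsv(
            rec.events, ev_dir / f"{rec.subject_id}_age{rec.age_months}m_events.tsv"
        )
        if cfg.get("write_edf", False):
            raw_dir = out / "raw"
            raw_dir.mkdir(exist_ok=True)
            eio.write_edf(rec, raw_dir / f"{rec.subject_id}_age{rec.age_months}m.edf")
    outcomes.to_csv(out / "outcomes.csv", index=False)
    return recordings, outcomes, montage


def stage_preprocess(recordings, montage: Montage, cfg: dict, out: Path):
    pcfg = PreprocConfig(**cfg.get("preprocess", {}))
    erps = []
    retention_rows = []
    for rec in recordings:
        erp = preprocess_recording(rec, montage, pcfg)
        erps.append(erp)
        for cond, n in erp.n_retained.items():
            retention_rows.append(
                (rec.subject_id, rec.group, rec.age_months, cond, n, cond in erp.excluded)
            )
    retention = pd.DataFrame(
        retention_rows,
        columns=["subject", "group", "age", "condition", "n_retained", "excluded"],
    )
    retention.to_csv(out / "retention.csv", index=False)
    log.info("preprocess: %d sessions, mean retained trials %.1f",
             len(erps), retention["n_retained"].mean())
    return erps, retention


def stage_features(erps, montage: Montage, out: Path):
    cset = build_contrasts(erps, montage)
    wtab = windowed_means(cset)
    finputs = factor_input_means(cset)
    _write_contrasts(cset, out / "contrasts.csv")
    wtab.to_csv(out / "window_table.csv", index=False)
    finputs.to_csv(out / "factor_inputs.csv", index=False)
    log.info("features: %d contrast waveforms, %d window rows",
             len(cset.index), len(wtab))
    return cset, wtab, finputs


def _write_contrasts(cset: ContrastWaveformSet, path: Path) -> None:
    wave_df = pd.DataFrame(
        cset.waveforms, columns=[f"t{int(t)}" for t in cset.times]
    )
    pd.concat([cset.index.reset_index(drop=True), wave_df], axis=1).to_csv(
        path, index=False
    )


def _read_contrasts(path: Path) -> ContrastWaveformSet:
    wide = pd.read_csv(path)
    tcols = [c for c in wide.columns if c.startswith("t") and c[1:].isdigit()]
    times = np.array([float(c[1:]) for c in tcols])
    index = wide.drop(columns=tcols)
    return ContrastWaveformSet(index=index, waveforms=wide[tcols].to_numpy(), times=times)


def stage_runtest(cset: ContrastWaveformSet, cfg: dict, out: Path, seed: int):
    """Run-length criterion per contrast x region x group x age.

    phi is by default pooled across all analysed datasets (matching the
    single value reported for real data); mode "per_dataset" estimates
    it per contrast/region/group/age instead.
    """
    rcfg = RunTestConfig(**{**cfg.get("runtest", {}), "seed": seed})
    phi_mode = cfg.get("phi_mode", "pooled")
    groups = sorted(cset.index["group"].unique())
    ages = sorted(cset.index["age"].unique())

    datasets = []
    for contrast in RUNTEST_CONTRASTS:
        for region in REGIONS:
            for group in groups:
                for age in ages:
                    idx, waves = cset.select(contrast, region, SITE_COLLAPSED, group, age)
                    if len(idx) >= 3:
                        datasets.append((contrast, region, group, age, waves))
    if not datasets:
        raise ValueError("no datasets with >= 3 subjects for the run test")
    phis = {(c, r, g, a): estimate_lag1(w, rcfg.lag)[0] for c, r, g, a, w in datasets}
    pooled_phi = float(np.mean(list(phis.values())))
    log.info("runtest: pooled lag-1 autocorrelation %.3f over %d datasets",
             pooled_phi, len(datasets))

    null_cache: dict[tuple, object] = {}
    rows = []
    traces = []
    for contrast, region, group, age, waves in datasets:
        phi = pooled_phi if phi_mode == "pooled" else phis[(contrast, region, group, age)]
        n = waves.shape[0]
        key = (round(phi, 6), n, waves.shape[1])
        if key not in null_cache:
            null_cache[key] = simulate_null(phi, n, waves.shape[1], rcfg)
        null = null_cache[key]
        t, p = pointwise_paired_t(waves, np.zeros_like(waves))
        det = detect_intervals(t, p, cset.times, null, rcfg.alpha)
        for onset, offset in det.intervals:
            rows.append((contrast, region, group, age, onset, offset,
                         null.threshold, phi, n))
        if not det.intervals:
            rows.append((contrast, region, group, age, np.nan, np.nan,
                         null.threshold, phi, n))
        traces.append((contrast, region, group, age, det))
    intervals = pd.DataFrame(
        rows,
        columns=["contrast", "region", "group", "age", "onset_ms", "offset_ms",
                 "threshold_run", "phi", "n"],
    )
    intervals.to_csv(out / "intervals.csv", index=False)
    return intervals, traces


def stage_stats(wtab: pd.DataFrame, finputs: pd.DataFrame, outcomes: pd.DataFrame,
                cfg: dict, out: Path):
    # windowed mixed models per contrast x region with Bonferroni follow-ups
    effect_rows, emm_rows, follow_rows = [], [], []
    for contrast in cfg.get("lmm_contrasts", LMM_CONTRASTS):
        for region in REGIONS:
            spec = ModelSpec(contrast=contrast, region=region)
            try:
                fit = fit_window_lmm(wtab, spec)
            except (ValueError, RuntimeError) as exc:
                log.warning("stats: model %s/%s failed: %s", contrast, region, exc)
                continue
            eff = fit.effects.copy()
            eff.insert(0, "region", region)
            eff.insert(0, "contrast", contrast)
            effect_rows.append(eff)
            emm = fit.emm.copy()
            emm.insert(0, "region", region)
            emm.insert(0, "contrast", contrast)
            emm_rows.append(emm)
            fu, adj_alpha = pairwise_followup(fit)
            fu.insert(0, "region", region)
            fu.insert(0, "contrast", contrast)
            fu["adjusted_alpha"] = adj_alpha
            follow_rows.append(fu)
    effects = pd.concat(effect_rows, ignore_index=True) if effect_rows else pd.DataFrame()
    emms = pd.concat(emm_rows, ignore_index=True) if emm_rows else pd.DataFrame()
    follows = pd.concat(follow_rows, ignore_index=True) if follow_rows else pd.DataFrame()
    effects.to_csv(out / "lmm_effects.csv", index=False)
    emms.to_csv(out / "lmm_emm.csv", index=False)
    follows.to_csv(out / "lmm_followups.csv", index=False)

    # component analysis on the eight 100-500 ms variables (ages stacked)
    variables = factor_variable_names()
    solution = None
    try:
        solution = pca_oblimin(finputs, variables)
        solution.loadings.to_csv(out / "pca_loadings.csv")
        solution.scores.to_csv(out / "factor_scores.csv", index=False)
        log.info("stats: retained %d components (%s)",
                 len(solution.component_names), ", ".join(solution.component_names))
    except ValueError as exc:
        log.warning("stats: component analysis unavailable: %s", exc)

    # outcome composites and correlations with 10-month factor scores
    scored = score_composites(outcomes)
    corr = pd.DataFrame()
    partials = []
    if solution is not None and solution.component_names:
        scores10 = solution.scores[solution.scores["age"] == 10]
        merged = scores10.merge(scored, on=["subject", "group"], how="inner")
        pairs = [
            (comp, y)
            for comp in solution.component_names
            for y in ("ibqr_activity", "aosi_total",
                      "language_comprehension", "language_production")
        ]
        corr = correlate_outcomes(merged, pairs)
        comp = solution.component_names[-1]  # standards-related component
        for x, ctrl in (("aosi_total", "ibqr_activity"), ("ibqr_activity", "aosi_total")):
            try:
                r, df, p = partial_correlate(merged, comp, x, ctrl)
                partials.append((comp, x, ctrl, r, df, p))
            except ValueError as exc:
                log.warning("stats: partial correlation %s~%s|%s unavailable: %s",
                            comp, x, ctrl, exc)
    corr.to_csv(out / "correlations.csv", index=False)
    pd.DataFrame(
        partials, columns=["x", "y", "control", "r", "df", "p"]
    ).to_csv(out / "partial_correlations.csv", index=False)
    return effects, emms, follows, solution, corr


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_contrast(
    cset: ContrastWaveformSet,
    contrast: str,
    region: str,
    intervals: pd.DataFrame,
    path: str | Path,
) -> Path:
    """Group/age mean waveforms with SEM bands and significance bars."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for group in sorted(cset.index["group"].unique()):
        for age in sorted(cset.index["age"].unique()):
            _, waves = cset.select(contrast, region, SITE_COLLAPSED, group, age)
            if waves.shape[0] == 0:
                continue
            m = waves.mean(axis=0)
            sem = waves.std(axis=0, ddof=1) / np.sqrt(waves.shape[0])
            ax.plot(cset.times, m, label=f"{group} {age}m")
            ax.fill_between(cset.times, m - sem, m + sem, alpha=0.2)
    sub = intervals[
        (intervals["contrast"] == contrast)
        & (intervals["region"] == region)
        & intervals["onset_ms"].notna()
    ]
    y0 = ax.get_ylim()[0]
    for _, row in sub.iterrows():
        ax.hlines(y0, row["onset_ms"], row["offset_ms"], colors="k", linewidth=4)
    ax.axhline(0.0, color="grey", linewidth=0.5)
    ax.set_xlabel("time after sound onset (ms)")
    ax.set_ylabel("amplitude (µV)")
    ax.set_title(f"{contrast} — {region}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    stop_after: str | None = None,
    resume: bool = True,
) -> dict:
    """Execute the pipeline and return the run manifest.

    ``stop_after`` may name a stage (simulate, preprocess, features,
    runtest, stats) to end early; ``resume`` reuses cached feature
    tables in ``out_dir`` when present.
    """
    if not isinstance(config, dict):
        config = eio.load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
    }

    feature_files = [out / "contrasts.csv", out / "window_table.csv",
                     out / "factor_inputs.csv", out / "outcomes.csv"]
    cached = resume and all(f.exists() for f in feature_files)
    if cached:
        log.info("resuming from cached feature tables in %s", out)
        cset = _read_contrasts(out / "contrasts.csv")
        wtab = pd.read_csv(out / "window_table.csv")
        finputs = pd.read_csv(out / "factor_inputs.csv")
        outcomes = pd.read_csv(out / "outcomes.csv")
        manifest["stages"]["features"] = {"cached": True}
    else:
        recordings, outcomes, montage = stage_simulate(config, out, seed)
        manifest["stages"]["simulate"] = {
            "n_sessions": len(recordings),
            "events_dir": str(out / "events"),
            "outcomes": str(out / "outcomes.csv"),
        }
        if stop_after == "simulate":
            eio.write_manifest(manifest, out / "manifest.json")
            return manifest
        erps, retention = stage_preprocess(recordings, montage, config, out)
        manifest["stages"]["preprocess"] = {
            "retention": str(out / "retention.csv"),
            "mean_retained": float(retention["n_retained"].mean()),
        }
        if stop_after == "preprocess":
            eio.write_manifest(manifest, out / "manifest.json")
            return manifest
        cset, wtab, finputs = stage_features(erps, montage, out)
        manifest["stages"]["features"] = {
            "contrasts": str(out / "contrasts.csv"),
            "window_table": str(out / "window_table.csv"),
            "factor_inputs": str(out / "factor_inputs.csv"),
        }
    if stop_after == "features":
        eio.write_manifest(manifest, out / "manifest.json")
        return manifest

    intervals, _ = stage_runtest(cset, config, out, seed)
    manifest["stages"]["runtest"] = {
        "intervals": str(out / "intervals.csv"),
        "n_detected": int(intervals["onset_ms"].notna().sum()),
    }
    if config.get("plots", True):
        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        for contrast in RUNTEST_CONTRASTS:
            for region in REGIONS:
                plot_contrast(
                    cset, contrast, region, intervals,
                    fig_dir / f"{contrast}_{region}.png",
                )
    if stop_after == "runtest":
        eio.write_manifest(manifest, out / "manifest.json")
        return manifest

    stage_stats(wtab, finputs, outcomes, config, out)
    manifest["stages"]["stats"] = {
        "lmm_effects": str(out / "lmm_effects.csv"),
        "correlations": str(out / "correlations.csv"),
    }
    eio.write_manifest(manifest, out / "manifest.json")
    return manifest


def demo_config() -> dict:
    """Small end-to-end configuration (runs in minutes on one CPU)."""
    return {
        "seed": 7,
        "paradigm": {"n_trains": 40, "session_cap_minutes": 4.0},
        "noise": {"std": 20.0},
        "design": {"n_td": 8, "n_nf1": 8},
        "montage": "default",
        "runtest": {"n_sims": 1000},
        "plots": True,
    }
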