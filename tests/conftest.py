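import numpy as np
import pytest

from erptrains.montage import default_montage
from erptrains.preprocess import PreprocConfig, preprocess_recording
from erptrains.simulate import (
    NoiseSpec,
    ParadigmConfig,
    default_effects,
    generate_subject_recording,
)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def effects():
    return default_effects()


@pytest.fixture(scope="session")
def noiseless_paradigm():
    # no ISI jitter: templates end by 440 ms, so at the fixed 550 ms
    # asynchrony every epoch's baseline window is free of neighbours
    return ParadigmConfig(n_trains=15, isi_jitter_halfwidth=0.0)


@pytest.fixture(scope="session")
def noiseless_erp(noiseless_paradigm, effects, montage):
    """One noiseless subject preprocessed end to end (planted templates)."""
    rec = generate_subject_recording(
        noiseless_paradigm, effects, NoiseSpec(std=0.0), montage,
        subject_id="sub-clean", group="TD", age_months=5, seed=3,
    )
    cfg = PreprocConfig(min_trials=5)
    return preprocess_recording(rec, montage, cfg)


@pytest.fixture(scope="session")
def noisy_erps(effects, montage):
    """Small noisy cohort of preprocessed sessions (two groups, two ages)."""
    cfg = ParadigmConfig(n_trains=30, session_cap_minutes=4.0)
    noise = NoiseSpec(std=15.0, artifact_rate=1.0)
    pcfg = PreprocConfig()
    erps = []
    seed = 100
    for group in ("TD", "NF1"):
        for i in range(3):
            for age in (5, 10):
                rec = generate_subject_recording(
                    cfg, effects, noise, montage,
                    subject_id=f"sub-{group}{i}", group=group,
                    age_months=age, seed=seed,
                )
                seed += 1
                erps.append(preprocess_recording(rec, montage, pcfg))
    return erps
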