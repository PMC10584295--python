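"""Shared fixtures: small, fast synthetic studies (10 Hz, minutes-long)."""

import numpy as np
import pytest

from refluxion.io import AnnotationInterval, ImpedanceStudy
from refluxion.synthetic import SyntheticConfig, generate_study


def make_flat_study(duration_s=600.0, rate=10.0, level=2000.0, ph=6.5,
                    annotations=(), study_id="flat"):
    """A constant-baseline study with no events."""
    n = int(round(duration_s * rate))
    return ImpedanceStudy(
        study_id=study_id,
        sampling_rate_hz=rate,
        impedance=np.full((6, n), float(level)),
        ph=np.full((2, n), float(ph)),
        annotations=list(annotations),
        metadata={"duration_s": float(duration_s)},
    ).validate()


def add_drop(study, channels, onset_s, duration_s, depth, lag_s=0.0):
    """Multiplicative square drop on the given channels (first channel at
    onset, later channels delayed by lag_s each)."""
    rate = study.sampling_rate_hz
    for j, c in enumerate(channels):
        i0 = int(round((onset_s + j * lag_s) * rate))
        i1 = int(round((onset_s + j * lag_s + duration_s) * rate))
        study.impedance[c, i0:i1] *= (1.0 - depth)
    return study


@pytest.fixture(scope="session")
def quick_config():
    """1-hour desk-scale generator config (one meal, default rates)."""
    return SyntheticConfig(duration_s=3600.0, meals=((1700.0, 2000.0),))


@pytest.fixture(scope="session")
def quick_study(quick_config):
    return generate_study(quick_config, seed=11)


@pytest.fixture(scope="session")
def labeled_clip_splits():
    """Small train/val clip splits from distinct studies."""
    from refluxion.candidates import detect_candidates, extract_clips

    cfg = SyntheticConfig(duration_s=1800.0, meals=())
    train, val = [], []
    for i in range(6):
        study, gold = generate_study(cfg, seed=100 + i)
        study.study_id = f"s{i:02d}"
        cands = detect_candidates(study)
        clips = extract_clips(study, cands, gold)
        (train if i < 4 else val).extend(clips)
    return train, val
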