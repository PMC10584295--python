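"""Signal-processing front end: meal exclusion, baseline estimation,
high-sensitivity candidate detection, and 60-second clip extraction.

The detector is deliberately permissive and direction-agnostic: any
interval in which at least ``min_channels`` (adjacent, by default)
impedance channels are simultaneously below ``drop_fraction`` of their
local rolling-median baseline for at least ``min_drop_duration_s`` becomes
a candidate — swallows and multi-channel artifacts included.  Separating
true retrograde reflux events from those hard negatives is the
classifier's job, not the detector's.

Baselines are centered rolling medians over a window (default 5 min) long
enough that even a 30-second event occupies a small minority of it; all
thresholds are baseline-relative, so the
candidate set is invariant under uniform scaling of the impedance values.
Studies whose distal baseline sits below a configurable floor (default
750 ohm) are flagged for exclusion rather than silently analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import EventRecord, ImpedanceStudy, ValidationError, merge_intervals

__all__ = [
    "Clip",
    "DetectorConfig",
    "exclude_meals",
    "compute_baseline",
    "study_baselines",
    "flag_low_baseline",
    "detect_candidates",
    "extract_clips",
    "tile_clips",
]

CLIP_DURATION_S = 60.0


@dataclass
class Clip:
    """A 60-second, baseline-normalized window of the 6-channel array."""

    study_id: str
    start_s: float
    data: np.ndarray  # (6, L), fractions of local baseline
    duration_s: float = CLIP_DURATION_S
    label: Optional[bool] = None
    candidate_onset_s: Optional[float] = None

    def __post_init__(self):
        if self.duration_s != CLIP_DURATION_S:
            raise ValidationError(f"clip duration must be {CLIP_DURATION_S} s")
        if self.data.ndim != 2 or self.data.shape[0] != 6:
            raise ValidationError(f"clip data must be (6, L), got {self.data.shape}")
        if np.any(self.data < 0):
            raise ValidationError("clip data must be >= 0")


@dataclass(frozen=True)
class DetectorConfig:
    """Peak-finding detector parameters (all baseline-relative)."""

    drop_fraction: float = 0.5
    min_channels: int = 2
    adjacency_required: bool = True
    min_drop_duration_s: float = 3.0
    baseline_window_s: float = 300.0
    merge_gap_s: float = 5.0
    low_baseline_floor_ohm: float = 750.0

    def __post_init__(self):
        if not (0.0 < self.drop_fraction < 1.0):
            raise ValidationError("drop_fraction must be in (0, 1)")
        if not (2 <= self.min_channels <= 6):
            raise ValidationError("min_channels must be in 2..6")


def exclude_meals(study: ImpedanceStudy) -> list:
    """Complement of the union of meal annotations within [0, duration)."""
    meals = merge_intervals([(m.start_s, m.end_s) for m in study.meals()])
    out, cur = [], 0.0
    for a, b in meals:
        a = max(a, 0.0)
        if a > cur:
            out.append((cur, a))
        cur = max(cur, b)
    if cur < study.duration_s:
        out.append((cur, study.duration_s))
    return out


def compute_baseline(trace, window_s: float, sampling_rate_hz: float) -> np.ndarray:
    """Centered rolling-median baseline; truncated windows at the edges.

    The window is the nearest odd number of samples to
    ``window_s * sampling_rate_hz`` so the window is symmetric around each
    sample.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size == 0:
        raise ValidationError("trace must be a non-empty 1-D sequence")
    half = max(int(round(window_s * sampling_rate_hz)) // 2, 0)
    window = 2 * half + 1
    return (
        pd.Series(trace)
        .rolling(window=window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def study_baselines(study: ImpedanceStudy, window_s: float) -> np.ndarray:
    """Per-channel rolling-median baselines, shape (6, T)."""
    return np.vstack([
        compute_baseline(study.impedance[c], window_s, study.sampling_rate_hz)
        for c in range(6)
    ])


def flag_low_baseline(study: ImpedanceStudy, floor_ohm: float = 750.0,
                      window_s: float = 300.0) -> bool:
    """True iff the distal channel's median baseline over non-meal time is
    strictly below ``floor_ohm`` (such studies are excluded, not analyzed)."""
    base = compute_baseline(study.impedance[0], window_s, study.sampling_rate_hz)
    mask = np.zeros(study.n_samples, dtype=bool)
    rate = study.sampling_rate_hz
    for a, b in exclude_meals(study):
        mask[int(round(a * rate)):int(round(b * rate))] = True
    if not mask.any():
        return True
    return bool(np.median(base[mask]) < floor_ohm)


def _runs(mask: np.ndarray):
    """Start/stop index pairs of True runs in a boolean vector."""
    diff = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def detect_candidates(study: ImpedanceStudy, config: DetectorConfig = DetectorConfig()) -> list:
    """High-sensitivity multi-channel drop detection.

    A candidate is a maximal interval where >= ``min_channels`` channels
    (required adjacent by default) sit simultaneously below
    ``drop_fraction`` x their rolling-median baseline for at least
    ``min_drop_duration_s``; candidates closer than ``merge_gap_s`` are
    merged, and meal time is excluded entirely.  Onset is the first
    below-threshold crossing of the distal-most participating channel.
    """
    study.validate()
    rate = study.sampling_rate_hz
    base = study_baselines(study, config.baseline_window_s)
    below = study.impedance < config.drop_fraction * base  # (6, T)

    k = config.min_channels
    if config.adjacency_required:
        # any run of k consecutive channels simultaneously below
        ok = np.zeros(study.n_samples, dtype=bool)
        for c0 in range(0, 7 - k):
            ok |= below[c0:c0 + k].all(axis=0)
    else:
        ok = below.sum(axis=0) >= k

    # zero out meal time
    mask = np.zeros(study.n_samples, dtype=bool)
    for a, b in exclude_meals(study):
        mask[int(round(a * rate)):int(round(b * rate))] = True
    ok &= mask

    # merge nearby runs first (noise can fragment one drop), then require
    # the merged interval to persist for min_drop_duration_s
    merged = []
    gap = int(round(config.merge_gap_s * rate))
    for s, e in _runs(ok):
        if merged and s - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    min_len = int(round(config.min_drop_duration_s * rate))
    merged = [(s, e) for s, e in merged if e - s >= min_len]

    out = []
    for s, e in merged:
        chans = np.flatnonzero(below[:, s:e].any(axis=1))
        c0 = int(chans.min())
        onset_idx = s + int(np.flatnonzero(below[c0, s:e])[0])
        out.append(EventRecord(
            onset_s=onset_idx / rate,
            end_s=e / rate,
            proximal_extent=int(chans.max()) + 1,
            source="software",
            is_event=None,
        ))
    return out


def _clip_window(onset_s: float, duration_s: float, rate: float):
    L = int(round(CLIP_DURATION_S * rate))
    n = int(round(duration_s * rate))
    i0 = int(round((onset_s - CLIP_DURATION_S / 2) * rate))
    i0 = min(max(i0, 0), max(n - L, 0))  # shift inward at recording edges
    return i0, L


def extract_clips(study: ImpedanceStudy, candidates: Sequence[EventRecord],
                  gold: Optional[Sequence[EventRecord]] = None,
                  label_tolerance_s: float = 5.0,
                  baseline_window_s: float = 300.0) -> list:
    """One 60-s baseline-normalized clip per candidate, centered on its onset.

    Windows are shifted inward at recording edges.  With ``gold`` given, a
    clip is labeled positive iff a gold event with ``is_event=True`` has its
    onset inside the window and within ``label_tolerance_s`` of the
    candidate onset.
    """
    study.validate()
    rate = study.sampling_rate_hz
    base = study_baselines(study, baseline_window_s)
    norm = study.impedance / np.clip(base, 1e-9, None)
    clips = []
    pos_onsets = (np.array([g.onset_s for g in gold if g.is_event])
                  if gold is not None else None)
    for cand in candidates:
        if not (0.0 <= cand.onset_s <= study.duration_s):
            raise ValidationError(
                f"candidate onset {cand.onset_s} outside study [0, {study.duration_s}]"
            )
        i0, L = _clip_window(cand.onset_s, study.duration_s, rate)
        data = norm[:, i0:i0 + L].copy()
        label = None
        if pos_onsets is not None:
            start_s = i0 / rate
            inside = (pos_onsets >= start_s) & (pos_onsets < start_s + CLIP_DURATION_S)
            close = np.abs(pos_onsets - cand.onset_s) <= label_tolerance_s
            label = bool(np.any(inside & close))
        clips.append(Clip(study_id=study.study_id, start_s=i0 / rate, data=data,
                          label=label, candidate_onset_s=cand.onset_s))
    return clips


def tile_clips(study: ImpedanceStudy, gold: Optional[Sequence[EventRecord]] = None,
               stride_s: float = 60.0, baseline_window_s: float = 300.0) -> list:
    """Alternative fixed-tiling mode: non-candidate-centered 60-s windows.

    Windows intersecting meals are dropped.  Labels (when ``gold`` given)
    mark windows containing a true event onset.
    """
    study.validate()
    rate = study.sampling_rate_hz
    base = study_baselines(study, baseline_window_s)
    norm = study.impedance / np.clip(base, 1e-9, None)
    L = int(round(CLIP_DURATION_S * rate))
    meals = merge_intervals([(m.start_s, m.end_s) for m in study.meals()])
    pos_onsets = (np.array([g.onset_s for g in gold if g.is_event])
                  if gold is not None else None)
    clips = []
    start = 0.0
    while start + CLIP_DURATION_S <= study.duration_s + 1e-9:
        if not any(start < b and start + CLIP_DURATION_S > a for a, b in meals):
            i0 = int(round(start * rate))
            label = None
            if pos_onsets is not None:
                label = bool(np.any((pos_onsets >= start)
                                    & (pos_onsets < start + CLIP_DURATION_S)))
            clips.append(Clip(study_id=study.study_id, start_s=start,
                              data=norm[:, i0:i0 + L].copy(), label=label))
        start += stride_s
    return clips
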