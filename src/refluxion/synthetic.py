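"""Ground-truthed synthetic pH/impedance study generator.

Real 24-hour MII-pH recordings are not redistributable, so the pipeline is
exercised on simulated studies that reproduce the statistical structure the
detector and classifier rely on:

* **Reflux events** — retrograde impedance drops: the distal channels fall
  first and the drop propagates proximally with a fixed per-channel lag,
  reaching a configurable proximal extent (>= 2 adjacent channels).  Depth
  is a fraction of the local baseline; morphology is a short linear fall, a
  plateau, and an exponential recovery.
* **Swallows** — antegrade (proximal-to-distal) drops across all six
  channels, shallower and shorter than reflux events.  They trip any
  direction-agnostic candidate detector and serve as built-in hard
  negatives.
* **Artifacts** — brief single-channel drops that a multi-channel detector
  must ignore.
* **Acid events** — a configurable fraction of reflux events additionally
  pull the distal pH below 4; per-study acid hold times are allocated so
  the percent of non-meal time at pH < 4 matches the configured acid
  exposure target.
* **Meals** — patient-marked intervals with elevated impedance noise; no
  ground-truth event is placed in or near a meal.

Per-study event counts follow a zero-truncated Gaussian whose mean/SD are
the cohort calibration targets (test-set defaults: 45.3 (23.6) events and
3.1% (3.0) acid exposure per 24 h, pro-rated to the configured duration).

Simulated physician readers (:func:`simulate_readers`) mark each true event
with probability ``hit_rate`` under Gaussian onset jitter and add false
marks on quiet time, which is what makes the downstream two-reader
adjudication and kappa machinery testable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .io import AnnotationInterval, EventRecord, ImpedanceStudy, merge_intervals

__all__ = [
    "SyntheticConfig",
    "ReaderModel",
    "ConfigError",
    "generate_study",
    "generate_cohort",
    "cohort_study_params",
    "simulate_readers",
]


class ConfigError(ValueError):
    """A synthetic configuration that cannot be realized."""


SECONDS_PER_DAY = 24.0 * 3600.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    Rates are expressed per 24 h (events) or per hour (swallows, artifacts)
    and pro-rated to ``duration_s``.  Defaults are desk-scale: 4-hour
    studies at 10 Hz with the test-set calibration (45.3 (23.6) events and
    3.1% (3.0) acid exposure per 24 h equivalent).
    """

    duration_s: float = 4 * 3600.0
    sampling_rate_hz: float = 10.0
    baseline_ohm_mean: float = 2000.0
    baseline_ohm_sd: float = 200.0
    events_per_24h_mean: float = 45.3
    events_per_24h_sd: float = 23.6
    event_drop_fraction: float = 0.7
    event_duration_s_range: tuple = (10.0, 30.0)
    retrograde_lag_s: float = 0.5
    acid_event_fraction: float = 0.45
    acid_exposure_target_pct: float = 3.1
    acid_exposure_sd_pct: float = 3.0
    swallows_per_hour: float = 15.0
    swallow_drop_fraction: float = 0.6
    swallow_duration_s_range: tuple = (5.0, 10.0)
    swallow_lag_s: float = 0.3
    artifact_rate_per_hour: float = 4.0
    meals: Optional[tuple] = None  # None -> three 20-min meals, evenly placed
    noise_sd_ohm: float = 50.0
    drift_amplitude_ohm: float = 100.0
    ph_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ConfigError("duration_s and sampling_rate_hz must be positive")
        for name in ("events_per_24h_mean", "events_per_24h_sd", "swallows_per_hour",
                     "artifact_rate_per_hour", "acid_exposure_target_pct",
                     "acid_exposure_sd_pct", "noise_sd_ohm"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 < self.event_drop_fraction < 1.0):
            raise ConfigError("event_drop_fraction must be in (0, 1)")
        if not (0.0 <= self.acid_event_fraction <= 1.0):
            raise ConfigError("acid_event_fraction must be in [0, 1]")
        if self.meals is not None:
            for a, b in self.meals:
                if not (0 <= a < b <= self.duration_s):
                    raise ConfigError(
                        f"meal interval [{a}, {b}) outside [0, {self.duration_s}]"
                    )

    def meal_intervals(self) -> list:
        """Meal schedule; default is three 20-minute meals."""
        if self.meals is not None:
            return merge_intervals(self.meals)
        if self.duration_s < 3600.0:
            return []
        out = []
        for frac in (0.25, 0.55, 0.85):
            start = frac * self.duration_s
            out.append((start, min(start + 1200.0, self.duration_s)))
        return merge_intervals(out)


# the training-set calibration from the study cohort (mean (SD) events per
# study 51.2 (33.0); acid exposure 4.5% (7.9)) for convenience
TRAIN_CALIBRATION = dict(
    events_per_24h_mean=51.2, events_per_24h_sd=33.0,
    acid_exposure_target_pct=4.5, acid_exposure_sd_pct=7.9,
)
TEST_CALIBRATION = dict(
    events_per_24h_mean=45.3, events_per_24h_sd=23.6,
    acid_exposure_target_pct=3.1, acid_exposure_sd_pct=3.0,
)


@dataclass(frozen=True)
class ReaderModel:
    """An imperfect physician reader.

    Marks each true event with probability ``hit_rate`` (Gaussian onset
    jitter, SD ``onset_jitter_sd_s``) and adds ``false_marks_per_24h``
    spurious marks uniformly on non-meal, non-event time.  When
    ``mark_candidates`` is set, false marks snap to supplied non-event
    candidate onsets instead (emulating readers reviewing pre-marked
    software candidates).
    """

    name: str = "reader_A"
    hit_rate: float = 0.8
    false_marks_per_24h: float = 36.0
    onset_jitter_sd_s: float = 1.5
    seed: int = 0
    mark_candidates: bool = False

    def __post_init__(self):
        if not (0.0 <= self.hit_rate <= 1.0):
            raise ConfigError(f"hit_rate must be in [0, 1], got {self.hit_rate}")
        if self.false_marks_per_24h < 0:
            raise ConfigError("false_marks_per_24h must be >= 0")
        if self.onset_jitter_sd_s < 0:
            raise ConfigError("onset_jitter_sd_s must be >= 0")


# ---------------------------------------------------------------------------
# placement helpers

_MEAL_MARGIN_S = 45.0   # keeps 60-s candidate-centered clips clear of meals
_EDGE_MARGIN_S = 40.0
_DROP_GAP_S = 45.0      # quiet time demanded on both sides of every drop


def _allowed_intervals(duration_s, meals, max_dur):
    """Intervals where a drop onset may be placed."""
    blocked = [(a - _MEAL_MARGIN_S, b + _MEAL_MARGIN_S) for a, b in meals]
    blocked = merge_intervals(blocked) if blocked else []
    lo, hi = _EDGE_MARGIN_S, duration_s - _EDGE_MARGIN_S - max_dur
    out, cur = [], lo
    for a, b in blocked:
        if a > cur:
            out.append((cur, min(a, hi)))
        cur = max(cur, b)
        if cur >= hi:
            break
    if cur < hi:
        out.append((cur, hi))
    return [(a, b) for a, b in out if b - a > 1.0]


def _sample_onsets(rng, n, allowed, occupied, durations):
    """Rejection-sample ``n`` onsets in ``allowed``, respecting occupancy."""
    lengths = np.array([b - a for a, b in allowed])
    total = lengths.sum()
    if total <= 0:
        return []
    placed = []
    tries = 0
    i = 0
    while i < n and tries < 200 * max(n, 1):
        tries += 1
        u = rng.uniform(0, total)
        k = int(np.searchsorted(np.cumsum(lengths), u, side="right"))
        k = min(k, len(allowed) - 1)
        onset = allowed[k][0] + (u - (np.cumsum(lengths)[k] - lengths[k]))
        dur = durations[i]
        iv = (onset - _DROP_GAP_S, onset + dur + _DROP_GAP_S)
        if any(not (iv[1] <= a or iv[0] >= b) for a, b in occupied):
            continue
        occupied.append(iv)
        placed.append((onset, dur))
        i += 1
    return placed


def _drop_shape(n, fall_samples, plateau_samples, tau_samples):
    """Unit drop profile: linear fall, plateau, exponential recovery."""
    t = np.arange(n, dtype=float)
    s = np.ones(n)
    if fall_samples > 0:
        m = t < fall_samples
        s[m] = t[m] / fall_samples
    rec = t - fall_samples - plateau_samples
    m = rec > 0
    s[m] = np.exp(-rec[m] / max(tau_samples, 1e-9))
    return s


def _truncated_normal(rng, mean, sd):
    """Draw from a Gaussian truncated at zero (redraw method)."""
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return x
    return 0.0


def _gamma_with_moments(rng, mean, sd):
    """Gamma draw with the requested mean and SD (positive support)."""
    if mean <= 0:
        return 0.0
    if sd == 0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return float(rng.gamma(shape, scale))


# ---------------------------------------------------------------------------
# study generation


def generate_study(config: SyntheticConfig, seed: int, return_details: bool = False):
    """Generate one study and its ground-truth reflux events.

    Returns ``(study, events)`` where events carry ``source='gold'`` and
    ``is_event=True``; with ``return_details=True`` a third dict exposes
    generator internals (per-channel onsets, swallows, artifacts, acid
    allocation) for property tests.

    Identical ``(config, seed)`` gives bit-identical output.
    """
    rng = np.random.default_rng(seed)
    rate = config.sampling_rate_hz
    n = int(round(config.duration_s * rate))
    meals = config.meal_intervals()
    meal_span = sum(b - a for a, b in meals)
    if meal_span >= config.duration_s - 2 * _EDGE_MARGIN_S - 60.0:
        raise ConfigError("meals cover (nearly) the entire study; no event placement possible")

    frac_day = config.duration_s / SECONDS_PER_DAY
    if config.events_per_24h_mean == 0:
        n_events = 0
    else:
        n_events = int(round(_truncated_normal(
            rng, config.events_per_24h_mean, config.events_per_24h_sd) * frac_day))
    n_swallows = rng.poisson(config.swallows_per_hour * config.duration_s / 3600.0)
    n_artifacts = rng.poisson(config.artifact_rate_per_hour * config.duration_s / 3600.0)

    max_dur = max(config.event_duration_s_range[1],
                  config.swallow_duration_s_range[1], 6.0) + 15.0
    allowed = _allowed_intervals(config.duration_s, meals, max_dur)
    if n_events > 0 and not allowed:
        raise ConfigError("no placeable non-meal time for events")

    occupied: list = []
    ev_durs = rng.uniform(*config.event_duration_s_range, size=n_events)
    events = _sample_onsets(rng, n_events, allowed, occupied, ev_durs)
    sw_durs = rng.uniform(*config.swallow_duration_s_range, size=n_swallows)
    swallows = _sample_onsets(rng, int(n_swallows), allowed, occupied, sw_durs)
    ar_durs = rng.uniform(2.0, 5.0, size=n_artifacts)
    artifacts = _sample_onsets(rng, int(n_artifacts), allowed, occupied, ar_durs)

    # per-channel impedance: level + slow drift + noise, then multiplicative drops
    levels = np.clip(rng.normal(config.baseline_ohm_mean, config.baseline_ohm_sd, 6), 800.0, None)
    t = np.arange(n) / rate
    imp = np.empty((6, n))
    for c in range(6):
        phase = rng.uniform(0, 2 * np.pi)
        drift = config.drift_amplitude_ohm * np.sin(2 * np.pi * t / 3600.0 + phase)
        imp[c] = levels[c] + drift + rng.normal(0, config.noise_sd_ohm, n)

    def apply_drop(channel, onset_s, depth, fall_s, plateau_s, tau_s):
        i0 = int(round(onset_s * rate))
        length = int(round((fall_s + plateau_s + tau_s * 6.0) * rate))
        i1 = min(i0 + length, n)
        if i0 >= n or i1 <= i0:
            return
        s = _drop_shape(i1 - i0, fall_s * rate, plateau_s * rate, tau_s * rate)
        imp[channel, i0:i1] *= (1.0 - depth * s)

    details_events = []
    gold = []
    extents = rng.choice([2, 3, 4, 5, 6], size=len(events), p=[0.30, 0.30, 0.20, 0.12, 0.08])
    for (onset, dur), extent in zip(events, extents):
        chan_onsets = [onset + c * config.retrograde_lag_s for c in range(extent)]
        for c, c_on in enumerate(chan_onsets):
            apply_drop(c, c_on, config.event_drop_fraction,
                       fall_s=2.0, plateau_s=max(dur - 2.0, 1.0), tau_s=2.0)
        gold.append(EventRecord(onset_s=onset, end_s=onset + dur,
                                proximal_extent=int(extent), source="gold",
                                is_event=True))
        details_events.append(dict(onset_s=onset, duration_s=dur,
                                   proximal_extent=int(extent),
                                   channel_onsets_s=chan_onsets))

    details_swallows = []
    for onset, dur in swallows:
        chan_onsets = [onset + (5 - c) * config.swallow_lag_s for c in range(6)]
        for c, c_on in enumerate(chan_onsets):
            apply_drop(c, c_on, config.swallow_drop_fraction,
                       fall_s=1.5, plateau_s=max(dur - 1.5, 1.0), tau_s=2.0)
        details_swallows.append(dict(onset_s=onset, duration_s=dur,
                                     channel_onsets_s=chan_onsets))

    details_artifacts = []
    for onset, dur in artifacts:
        c = int(rng.integers(0, 6))
        apply_drop(c, onset, 0.8, fall_s=0.5, plateau_s=max(dur - 0.5, 0.5), tau_s=1.0)
        details_artifacts.append(dict(onset_s=onset, duration_s=dur, channel=c))

    # meals: elevated, noisy impedance
    meal_mask = np.zeros(n, dtype=bool)
    for a, b in meals:
        meal_mask[int(round(a * rate)):int(round(b * rate))] = True
    if meal_mask.any() and config.noise_sd_ohm > 0:
        imp[:, meal_mask] += rng.normal(0, 5 * config.noise_sd_ohm, (6, int(meal_mask.sum())))
    imp = np.clip(imp, 0.0, None)

    # pH traces; distal acid events realize the configured acid exposure target
    ph = np.empty((2, n))
    for r, base in enumerate((6.5, 6.8)):
        phase = rng.uniform(0, 2 * np.pi)
        wander = 0.3 * np.sin(2 * np.pi * t / 7200.0 + phase)
        ph[r] = base + wander + rng.normal(0, config.ph_noise_sd, n)

    acid_alloc = []
    gold_sorted = sorted(range(len(gold)), key=lambda i: gold[i].onset_s)
    if gold and config.acid_event_fraction > 0 and config.acid_exposure_target_pct > 0:
        n_acid = max(1, int(round(config.acid_event_fraction * len(gold))))
        acid_idx = sorted(rng.choice(len(gold_sorted), size=min(n_acid, len(gold_sorted)),
                                     replace=False).tolist())
        acid_onsets = [gold[gold_sorted[i]].onset_s for i in acid_idx]
        non_meal_samples = n - int(meal_mask.sum())
        required_s = config.acid_exposure_target_pct / 100.0 * non_meal_samples / rate
        caps = []
        for j, onset in enumerate(acid_onsets):
            nxt = acid_onsets[j + 1] if j + 1 < len(acid_onsets) else config.duration_s
            for a, _b in meals:
                if onset < a < nxt:
                    nxt = a
                    break
            caps.append(max(nxt - onset - 5.0, 2.0))
        caps = np.array(caps)
        w = rng.uniform(0.5, 1.5, len(caps))
        alloc = np.zeros(len(caps))
        remaining = required_s
        free = np.ones(len(caps), dtype=bool)
        for _ in range(20):
            if remaining <= 1e-9 or not free.any():
                break
            share = remaining * w * free / (w * free).sum()
            add = np.minimum(share, caps - alloc)
            alloc += add
            remaining -= add.sum()
            free = alloc < caps - 1e-9
        for onset, dur in zip(acid_onsets, alloc):
            if dur <= 0.2:
                continue
            i0 = int(round((onset + 1.0) * rate))
            hold = int(round(dur * rate))
            fall = int(round(0.5 * rate))
            i1 = min(i0 + fall + hold + fall, n)
            if i0 >= n:
                continue
            s = np.zeros(i1 - i0)
            k = np.arange(i1 - i0)
            s = np.clip(np.minimum(k / max(fall, 1), (fall + hold + fall - 1 - k) / max(fall, 1)), 0, 1)
            depth = ph[0, i0:i1] - 1.8
            ph[0, i0:i1] -= np.clip(depth, 0, None) * s
            acid_alloc.append(dict(onset_s=onset, acid_hold_s=float(dur)))
    ph = np.clip(ph, 0.0, 14.0)

    annotations = [AnnotationInterval("meal", a, b) for a, b in meals]
    study = ImpedanceStudy(
        study_id=f"synth-{seed}",
        sampling_rate_hz=rate,
        impedance=imp,
        ph=ph,
        annotations=annotations,
        metadata={"duration_s": float(config.duration_s), "on_ppi": False,
                  "indication": "GERD"},
    ).validate()
    gold = sorted(gold, key=lambda e: e.onset_s)
    if return_details:
        details = dict(events=details_events, swallows=details_swallows,
                       artifacts=details_artifacts, acid=acid_alloc,
                       baseline_levels_ohm=levels.tolist())
        return study, gold, details
    return study, gold


def cohort_study_params(config: SyntheticConfig, seed: int, n_studies: int):
    """Deterministic per-study (seed, config) derivation for a cohort.

    Study seeds come from a :class:`numpy.random.SeedSequence`; per-study
    acid exposure targets are Gamma draws with the configured cohort
    mean/SD (positive support with exact first two moments).
    """
    if n_studies < 1:
        raise ConfigError("n_studies must be >= 1")
    ss = np.random.SeedSequence(seed)
    study_seeds = [int(s) % (2 ** 31) for s in ss.generate_state(n_studies)]
    rng = np.random.default_rng(ss.spawn(1)[0])
    out = []
    for i in range(n_studies):
        target = _gamma_with_moments(rng, config.acid_exposure_target_pct,
                                     config.acid_exposure_sd_pct)
        out.append((study_seeds[i], replace(config, acid_exposure_target_pct=target,
                                            seed=study_seeds[i])))
    return out


def generate_cohort(n_studies: int, config: SyntheticConfig, seed: int):
    """Generate ``n_studies`` independent studies with derived seeds."""
    out = []
    for i, (study_seed, cfg_i) in enumerate(cohort_study_params(config, seed, n_studies)):
        study, gold = generate_study(cfg_i, study_seed)
        study.study_id = f"synth-{seed}-{i:03d}"
        out.append((study, gold))
    return out


# ---------------------------------------------------------------------------
# simulated readers


def simulate_readers(gold: Sequence[EventRecord], candidates: Sequence[EventRecord],
                     reader: ReaderModel, duration_s: float,
                     meals: Sequence[tuple] = ()) -> list:
    """Simulate one physician reader's marks on a study.

    Each gold event is marked with probability ``hit_rate`` under Gaussian
    onset jitter; false marks land uniformly on non-meal, non-event time
    (or, when ``reader.mark_candidates`` is set and non-event ``candidates``
    exist, on a random subset of those candidates).  Output is sorted and
    carries the reader's identity as source.
    """
    rng = np.random.default_rng(reader.seed)
    marks = []
    for ev in sorted(gold, key=lambda e: e.onset_s):
        if rng.uniform() < reader.hit_rate:
            onset = max(ev.onset_s + rng.normal(0, reader.onset_jitter_sd_s), 0.0)
            marks.append(EventRecord(onset_s=onset, end_s=onset + (ev.end_s - ev.onset_s),
                                     proximal_extent=ev.proximal_extent,
                                     source=reader.name, is_event=None))
    n_false = rng.poisson(reader.false_marks_per_24h * duration_s / SECONDS_PER_DAY)
    if n_false > 0:
        if reader.mark_candidates and len(candidates) > 0:
            pool = [c for c in candidates
                    if not any(abs(c.onset_s - g.onset_s) <= 15.0 for g in gold)]
            if pool:
                idx = rng.choice(len(pool), size=min(n_false, len(pool)), replace=False)
                for i in idx:
                    c = pool[int(i)]
                    marks.append(EventRecord(onset_s=c.onset_s, end_s=c.end_s,
                                             proximal_extent=c.proximal_extent,
                                             source=reader.name, is_event=None))
                n_false = 0
        blocked = [(g.onset_s - 30.0, g.end_s + 30.0) for g in gold]
        blocked += [(a, b) for a, b in meals]
        blocked = merge_intervals(blocked) if blocked else []
        free, cur = [], 0.0
        for a, b in blocked:
            if a > cur:
                free.append((cur, a))
            cur = max(cur, b)
        if cur < duration_s:
            free.append((cur, duration_s))
        lengths = np.array([b - a for a, b in free])
        if lengths.sum() > 0:
            for _ in range(int(n_false)):
                u = rng.uniform(0, lengths.sum())
                k = min(int(np.searchsorted(np.cumsum(lengths), u, side="right")),
                        len(free) - 1)
                onset = free[k][0] + (u - (np.cumsum(lengths)[k] - lengths[k]))
                dur = rng.uniform(10.0, 20.0)
                marks.append(EventRecord(onset_s=onset,
                                         end_s=min(onset + dur, duration_s + dur),
                                         proximal_extent=2, source=reader.name,
                                         is_event=None))
    marks.sort(key=lambda e: (e.onset_s, e.end_s))
    return marks
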