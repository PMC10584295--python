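"""Logistic-regression sanity baseline over hand-crafted clip summaries.

Not part of the reflux-identification system proper — a deliberately
simple reference model used to sanity-check that the sequence classifier
earns its keep.  Features are per-channel summaries of the
baseline-normalized clip: depth and timing of the minimum, fraction of
time below the 50% criterion, and the distal-to-proximal ordering of the
per-channel minima (retrograde events have increasing time-of-minimum
from distal to proximal; swallows the reverse).
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .io import ValidationError

__all__ = ["clip_features", "SummaryFeatureBaseline"]


def clip_features(clip) -> np.ndarray:
    """Fixed-length feature vector for one clip."""
    d = clip.data  # (6, L) fractions of baseline
    L = d.shape[1]
    mins = d.min(axis=1)
    argmins = d.argmin(axis=1) / L
    below = (d < 0.5).mean(axis=1)
    # slope of time-of-minimum across channels: + for retrograde propagation
    x = np.arange(6)
    slope = np.polyfit(x, argmins, 1)[0]
    return np.concatenate([mins, argmins, below,
                           [d.min(), d.mean(), slope, (d < 0.5).any(axis=1).sum()]])


class SummaryFeatureBaseline:
    """Fit/predict wrapper mirroring the classifier interface."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=C, max_iter=2000, random_state=seed),
        )

    def fit(self, clips) -> "SummaryFeatureBaseline":
        labels = [c.label for c in clips]
        if any(lab is None for lab in labels):
            raise ValidationError("baseline requires labeled clips")
        X = np.stack([clip_features(c) for c in clips])
        self.model.fit(X, np.asarray(labels, dtype=bool))
        return self

    def predict(self, clips) -> np.ndarray:
        X = np.stack([clip_features(c) for c in clips])
        return self.model.predict_proba(X)[:, 1]
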