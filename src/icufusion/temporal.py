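"""Temporal branch: 48x17 hourly feature grid and its LSTM embedding.

Irregular measurements are binned to a dense T-hour grid (arithmetic mean of
all measurements of a feature landing in one hour), missing cells are filled
by forward-fill within the stay and by the feature's clinical normal value
before the first observation, everything is z-scored with training-split
statistics only, and a single-layer unidirectional LSTM consumes the T rows;
its last hidden state is the temporal embedding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .autodiff import Tensor
from .ingest import RawEvent
from .resources import feature_names, normal_values

logger = logging.getLogger(__name__)


@dataclass
class TemporalMatrix:
    """T x F grid of hourly feature values plus an observation mask.

    Before imputation unobserved cells are NaN; after
    :func:`impute_and_scale` all values are finite z-scores.
    """

    values: np.ndarray         # (T, F) float64
    observed_mask: np.ndarray  # (T, F) bool

    @property
    def n_hours(self) -> int:
        return self.values.shape[0]


def bin_hourly(events: Iterable[RawEvent], n_hours: int = 48) -> TemporalMatrix:
    """Average measurements per (hour, feature) cell.

    Events must not predate admission (negative times are an error upstream
    anchoring failed to catch); events at or beyond ``n_hours`` fall outside
    the observation grid and are ignored.
    """
    order = {f: i for i, f in enumerate(feature_names())}
    sums = np.zeros((n_hours, len(order)))
    counts = np.zeros((n_hours, len(order)))
    for ev in events:
        if ev.time < 0:
            raise ValueError(f"negative event time {ev.time} for stay {ev.stay_id}")
        t = int(math.floor(ev.time))
        if t >= n_hours:
            continue
        f = order[ev.feature_name]
        sums[t, f] += ev.value
        counts[t, f] += 1
    mask = counts > 0
    values = np.full_like(sums, np.nan)
    np.divide(sums, counts, out=values, where=mask)
    return TemporalMatrix(values=values, observed_mask=mask)


@dataclass
class TrainStats:
    """Per-feature imputation and scaling statistics, training split only."""

    mean: np.ndarray   # (F,)
    sd: np.ndarray     # (F,)
    normal: np.ndarray # (F,) clinical normal used before the first observation

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist(),
                "normal": self.normal.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TrainStats":
        return cls(*(np.asarray(d[k], dtype=np.float64) for k in ("mean", "sd", "normal")))


def compute_train_stats(matrices: Sequence[TemporalMatrix]) -> TrainStats:
    """Observed-cell mean/sd per feature over the training matrices.

    Zero-variance (or never-observed) features get sd clamped to 1 so
    z-scoring stays defined.
    """
    feats = feature_names()
    normal = np.array([normal_values()[f] for f in feats])
    if not matrices:
        return TrainStats(mean=normal.copy(), sd=np.ones(len(feats)), normal=normal)
    stacked = np.concatenate([m.values for m in matrices], axis=0)
    masks = np.concatenate([m.observed_mask for m in matrices], axis=0)
    mean = np.zeros(len(feats))
    sd = np.ones(len(feats))
    for f in range(len(feats)):
        obs = stacked[masks[:, f], f]
        if obs.size == 0:
            mean[f] = normal[f]
            logger.info("feature %s never observed in training; using normal value", feats[f])
            continue
        mean[f] = obs.mean()
        s = obs.std()
        if s <= 1e-12:
            logger.info("feature %s has zero variance in training; sd clamped to 1", feats[f])
            s = 1.0
        sd[f] = s
    return TrainStats(mean=mean, sd=sd, normal=normal)


def impute_and_scale(matrix: TemporalMatrix, stats: TrainStats) -> TemporalMatrix:
    """Forward-fill within the stay, clinical-normal before the first
    observation, then z-score with training statistics.  Causal: hour t is
    never filled from hours > t."""
    T, F = matrix.values.shape
    filled = matrix.values.copy()
    for f in range(F):
        last = stats.normal[f]
        for t in range(T):
            if matrix.observed_mask[t, f]:
                last = filled[t, f]
            else:
                filled[t, f] = last
    z = (filled - stats.mean) / stats.sd
    return TemporalMatrix(values=z, observed_mask=matrix.observed_mask.copy())


# ---------------------------------------------------------------------------
# LSTM encoder
# ---------------------------------------------------------------------------

def init_lstm_params(n_features: int, hidden_dim: int,
                     rng: np.random.Generator) -> dict[str, Tensor]:
    """Glorot-uniform weights; forget-gate bias starts at 1."""
    def glorot(fan_in, fan_out, shape):
        lim = math.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

    b = np.zeros(4 * hidden_dim)
    b[hidden_dim: 2 * hidden_dim] = 1.0
    return {
        "lstm_Wx": glorot(n_features, hidden_dim, (n_features, 4 * hidden_dim)),
        "lstm_Wh": glorot(hidden_dim, hidden_dim, (hidden_dim, 4 * hidden_dim)),
        "lstm_b": Tensor(b, requires_grad=True),
    }


def lstm_forward(x: np.ndarray, params: dict[str, Tensor]) -> Tensor:
    """Run the LSTM over a batch of grids; return the last hidden state.

    x: (B, T, F) finite array -> Tensor (B, H).  Gate layout along the last
    weight axis is [input, forget, cell, output].
    """
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in LSTM input; impute before encoding")
    B, T, F = x.shape
    H = params["lstm_Wh"].shape[0]
    h = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H)))
    for t in range(T):
        xt = Tensor(x[:, t, :])
        z = xt @ params["lstm_Wx"] + h @ params["lstm_Wh"] + params["lstm_b"]
        i = z[:, 0 * H: 1 * H].sigmoid()
        f = z[:, 1 * H: 2 * H].sigmoid()
        g = z[:, 2 * H: 3 * H].tanh()
        o = z[:, 3 * H: 4 * H].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
    return h


def lstm_encode(matrix: TemporalMatrix, params: dict[str, Tensor]) -> np.ndarray:
    """Temporal embedding of one stay: h_T as a plain (H,) vector."""
    out = lstm_forward(matrix.values[None, :, :], params)
    return out.data[0]
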