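"""Memory benchmark tasks: Memory Capacity and Sequence Recall.

Memory Capacity (MC)
    A scalar stream X(t) ~ Uniform(-0.5, 0.5) is fed through a single input
    neuron; one output per lag tau is trained to reconstruct the delayed
    input Y_tau(t) = X(t - tau). The per-lag score is the squared Pearson
    correlation rho^2(y_tau, yhat_tau) over the scored steps and

        MC = sum_tau rho^2(y_tau, yhat_tau)

    so MC is bounded by the number of lags. The per-lag curve is the
    forgetting curve.

Sequence Recall
    Two input channels: X1(t) ~ Uniform(0, 1) is a stream to memorize, X2(t)
    is a cue (0 = fixate, 1 = recall). Each trial is a fixation period of
    ``fixation_len`` steps followed by L recall steps during which the
    network must output, in order, the last L fixation values of X1. Targets
    are 0 during fixation and performance is the pooled R^2 over recall
    steps only (the fixation phase is trivially easy and would inflate the
    score).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "MemoryCapacityDataset",
    "SequenceRecallDataset",
    "EvalResult",
    "make_memory_capacity_data",
    "score_memory_capacity",
    "make_sequence_recall_data",
    "score_sequence_recall",
]


@dataclass(frozen=True)
class EvalResult:
    """Per-output scores and the aggregate (MC or recall R^2)."""

    per_output_scores: tuple[float, ...]
    aggregate: float
    n_scored_steps: int
    task: str
    metadata: dict | None = None


@dataclass(frozen=True)
class MemoryCapacityDataset:
    """Input stream and lagged targets; y[t, j] = x[t - lags[j]] (NaN where
    the lag reaches before the start of the series)."""

    x: np.ndarray          # (T, 1)
    y: np.ndarray          # (T, n_lags), NaN on undefined leading entries
    lags: tuple[int, ...]

    @property
    def n_steps(self) -> int:
        return self.x.shape[0]

    def split(self, n_train: int) -> tuple["MemoryCapacityDataset", "MemoryCapacityDataset"]:
        """Contiguous train/test split: first ``n_train`` steps, then the rest.

        Test targets still reference the full stream, so the test split has no
        undefined entries; its early steps should be covered by the transient
        discard because the reservoir restarts from a zero state.
        """
        if not 0 < n_train < self.n_steps:
            raise ValidationError("n_train must be in (0, n_steps)")
        train = MemoryCapacityDataset(self.x[:n_train], self.y[:n_train], self.lags)
        test = MemoryCapacityDataset(self.x[n_train:], self.y[n_train:], self.lags)
        return train, test

    def to_frame(self, y_hat: np.ndarray | None = None):
        """Tidy long-format export: columns (t, x1, lag, y_true[, y_hat])."""
        import pandas as pd

        t = np.arange(self.n_steps)
        frames = []
        for j, tau in enumerate(self.lags):
            rec = {"t": t, "x1": self.x[:, 0], "lag": tau, "y_true": self.y[:, j]}
            if y_hat is not None:
                rec["y_hat"] = np.asarray(y_hat)[:, j]
            frames.append(pd.DataFrame(rec))
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SequenceRecallDataset:
    """Concatenated trials of the sequence recall task.

    ``x`` has two columns (x1 = stream, x2 = cue); ``y`` is the single
    target; ``boundaries`` lists (fixation_start, recall_start, trial_end)
    per trial.
    """

    x: np.ndarray          # (T, 2)
    y: np.ndarray          # (T, 1)
    pattern_length: int
    fixation_len: int
    boundaries: tuple[tuple[int, int, int], ...]

    @property
    def n_steps(self) -> int:
        return self.x.shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.boundaries)

    @property
    def recall_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_steps, dtype=bool)
        for _, recall_start, trial_end in self.boundaries:
            mask[recall_start:trial_end] = True
        return mask

    def split(self, n_train_trials: int) -> tuple["SequenceRecallDataset", "SequenceRecallDataset"]:
        """Split at a trial boundary: first ``n_train_trials`` trials, then the rest."""
        if not 0 < n_train_trials < self.n_trials:
            raise ValidationError("n_train_trials must be in (0, n_trials)")
        cut = self.boundaries[n_train_trials - 1][2]
        train_b = self.boundaries[:n_train_trials]
        test_b = tuple(
            (fs - cut, rs - cut, te - cut) for fs, rs, te in self.boundaries[n_train_trials:]
        )
        train = SequenceRecallDataset(
            self.x[:cut], self.y[:cut], self.pattern_length, self.fixation_len, train_b
        )
        test = SequenceRecallDataset(
            self.x[cut:], self.y[cut:], self.pattern_length, self.fixation_len, test_b
        )
        return train, test

    def to_frame(self, y_hat: np.ndarray | None = None):
        """Tidy export: columns (t, x1, x2, y_true, phase, trial[, y_hat])."""
        import pandas as pd

        trial = np.zeros(self.n_steps, dtype=int)
        for i, (fs, _, te) in enumerate(self.boundaries):
            trial[fs:te] = i
        frame = pd.DataFrame({
            "t": np.arange(self.n_steps),
            "x1": self.x[:, 0],
            "x2": self.x[:, 1],
            "y_true": self.y[:, 0],
            "phase": np.where(self.recall_mask, "recall", "fixation"),
            "trial": trial,
        })
        if y_hat is not None:
            frame["y_hat"] = np.asarray(y_hat).reshape(-1)
        return frame


def make_memory_capacity_data(
    T: int, lags: Sequence[int], seed: int | None = None
) -> MemoryCapacityDataset:
    """Generate a memory-capacity dataset of ``T`` steps for the given lags.

    ``lags`` must be positive and strictly increasing; ``T`` must exceed the
    largest lag. X(t) ~ Uniform(-0.5, 0.5), deterministic under ``seed``.
    """
    lags = tuple(int(tau) for tau in lags)
    if not lags or any(tau <= 0 for tau in lags):
        raise ValidationError("lags must be positive integers")
    if any(b <= a for a, b in zip(lags, lags[1:])):
        raise ValidationError("lags must be strictly increasing")
    if T <= max(lags):
        raise DegenerateInputError(f"T={T} must exceed the largest lag {max(lags)}")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-0.5, 0.5, size=(T, 1))
    y = np.full((T, len(lags)), np.nan)
    for j, tau in enumerate(lags):
        y[tau:, j] = x[:-tau, 0]
    return MemoryCapacityDataset(x=x, y=y, lags=lags)


def _squared_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """rho^2 with the convention that a constant series scores 0."""
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    rho = np.corrcoef(a, b)[0, 1]
    if not np.isfinite(rho):
        return 0.0
    return float(min(rho * rho, 1.0))


def score_memory_capacity(
    y: np.ndarray,
    y_hat: np.ndarray,
    lags: Sequence[int],
    transient: int = 0,
    metadata: dict | None = None,
) -> EvalResult:
    """Per-lag rho^2 scores and their sum (the memory capacity).

    Rows before ``transient`` and rows where the target is undefined (NaN)
    are excluded per lag. A constant target or prediction scores 0 for that
    lag.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValidationError(f"shape mismatch: y {y.shape} vs y_hat {y_hat.shape}")
    lags = tuple(lags)
    if y.shape[1] != len(lags):
        raise ValidationError("one target column per lag required")
    t = np.arange(y.shape[0])
    scores = []
    n_scored = 0
    for j in range(len(lags)):
        valid = (t >= transient) & ~np.isnan(y[:, j])
        scores.append(_squared_pearson(y[valid, j], y_hat[valid, j]))
        n_scored = max(n_scored, int(valid.sum()))
    return EvalResult(
        per_output_scores=tuple(scores),
        aggregate=float(sum(scores)),
        n_scored_steps=n_scored,
        task="memory-capacity",
        metadata=metadata,
    )


def make_sequence_recall_data(
    n_trials: int,
    L: int,
    fixation_len: int | None = None,
    seed: int | None = None,
) -> SequenceRecallDataset:
    """Generate ``n_trials`` concatenated trials of the sequence recall task.

    Each trial: ``fixation_len`` fixation steps (x1 ~ Uniform(0, 1), cue
    x2 = 0, target 0) followed by ``L`` recall steps (x1 = 0, x2 = 1, target =
    the last L fixation values of x1, in presentation order). ``fixation_len``
    defaults to L (the shortest length that holds the full pattern).
    """
    if L < 1:
        raise ValidationError("pattern length L must be >= 1")
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if fixation_len is None:
        fixation_len = L
    if fixation_len < L:
        raise DegenerateInputError(
            f"fixation_len={fixation_len} < L={L}: the pattern would be truncated"
        )
    rng = np.random.default_rng(seed)
    trial_len = fixation_len + L
    T = n_trials * trial_len
    x = np.zeros((T, 2))
    y = np.zeros((T, 1))
    boundaries = []
    for trial in range(n_trials):
        fs = trial * trial_len
        rs = fs + fixation_len
        te = fs + trial_len
        stream = rng.uniform(0.0, 1.0, size=fixation_len)
        x[fs:rs, 0] = stream
        x[rs:te, 1] = 1.0
        y[rs:te, 0] = stream[-L:]
        boundaries.append((fs, rs, te))
    return SequenceRecallDataset(
        x=x, y=y, pattern_length=L, fixation_len=fixation_len,
        boundaries=tuple(boundaries),
    )


def score_sequence_recall(
    y: np.ndarray,
    y_hat: np.ndarray,
    boundaries: Sequence[tuple[int, int, int]],
    transient: int = 0,
    metadata: dict | None = None,
) -> EvalResult:
    """Pooled R^2 over recall steps only (fixation steps never contribute).

    R^2 = 1 - SS_res / SS_tot over the concatenated recall steps at or after
    ``transient``, with SS_tot about the mean of the true recall targets.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    y_hat = np.asarray(y_hat, dtype=float).reshape(-1)
    if y.shape != y_hat.shape:
        raise ValidationError(f"shape mismatch: y {y.shape} vs y_hat {y_hat.shape}")
    idx = []
    for _, recall_start, trial_end in boundaries:
        idx.extend(range(max(recall_start, transient), trial_end))
    idx = [i for i in idx if i < y.shape[0]]
    if not idx:
        raise DegenerateInputError("no recall steps to score after the transient")
    yt, yp = y[idx], y_hat[idx]
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    ss_res = float(np.sum((yt - yp) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return EvalResult(
        per_output_scores=(r2,),
        aggregate=float(r2),
        n_scored_steps=len(idx),
        task="sequence-recall",
        metadata=metadata,
    )
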