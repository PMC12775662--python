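"""Monte-Carlo engine: simulate temporal sequences of decay and recovery and
estimate the probability of retaining the skill over the horizon.

Each temporal sequence starts with the expert pool full at t = 0 and walks
through successive use intervals. An interval longer than the maximum
unused-retention time ``dt_max`` drops the continuous expert count below the
threshold and the skill is permanently lost; any shorter interval ends in a
use that instantly restores the pool. A sequence that reaches the horizon
``L`` without such a gap retains the skill. Retention probability is
estimated as the fraction of ``K`` independent sequences that retain,
``P_r = 1 - n_l / K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ModelParams
from .intervals import required_draw_count, sample_intervals

__all__ = ["SequenceOutcome", "RetentionEstimate", "run_sequence", "estimate_retention"]


@dataclass(frozen=True)
class SequenceOutcome:
    """Fate of a single temporal sequence.

    ``lost`` is True when some interval exceeded dt_max before the cumulative
    time passed the horizon; ``loss_time`` is then the instant the expert
    count crossed the threshold (time of the last use plus dt_max), and
    ``end_time`` equals it. A retained sequence has ``end_time`` at the first
    cumulative use time beyond the horizon. ``n_uses`` counts uses that
    occurred within the horizon.
    """

    lost: bool
    loss_time: float | None
    n_uses: int
    end_time: float

    def __post_init__(self) -> None:
        if self.lost and self.loss_time is None:
            raise ValueError("lost sequences must carry a loss_time")
        if not self.lost and self.loss_time is not None:
            raise ValueError("retained sequences have no loss_time")


@dataclass(frozen=True)
class RetentionEstimate:
    """Monte-Carlo estimate of the retention probability P_r = 1 - n_l / K."""

    p_r: float
    n_losses: int
    n_sequences: int
    std_error: float

    @classmethod
    def from_counts(cls, n_losses: int, n_sequences: int) -> "RetentionEstimate":
        p = 1.0 - n_losses / n_sequences
        se = math.sqrt(p * (1.0 - p) / n_sequences)
        return cls(p_r=p, n_losses=n_losses, n_sequences=n_sequences, std_error=se)


def run_sequence(
    params: ModelParams,
    random_stream: np.random.Generator,
    stream_id: str = "",
) -> SequenceOutcome:
    """Simulate one temporal sequence until loss or horizon.

    The loss test is strict: an interval exactly equal to dt_max leaves the
    expert count exactly at the threshold, which still counts as retained.
    Time advances by whole intervals; the sequence ends at the first
    cumulative time strictly beyond the horizon.
    """
    dt_max = params.delta_t_max
    L = params.horizon_L
    chunk = required_draw_count(L, params.theta)

    t = 0.0
    n_uses = 0
    while True:
        dts = sample_intervals(
            params.theta, params.nu, chunk, random_stream, stream_id
        ).intervals
        times = t + np.cumsum(dts)

        exceed = np.flatnonzero(dts > dt_max)
        past = np.flatnonzero(times > L)
        j = exceed[0] if exceed.size else None
        m = past[0] if past.size else None

        if j is not None and (m is None or j <= m):
            # the j-th interval outlasts dt_max before the horizon is reached
            last_use = times[j] - dts[j]
            loss_time = last_use + dt_max
            return SequenceOutcome(
                lost=True,
                loss_time=loss_time,
                n_uses=n_uses + j,
                end_time=loss_time,
            )
        if m is not None:
            # reached the horizon; uses at times <= L all succeeded
            return SequenceOutcome(
                lost=False,
                loss_time=None,
                n_uses=n_uses + int(m),
                end_time=float(times[m]),
            )
        # rare: 2L/theta draws did not cover the horizon — extend
        t = float(times[-1])
        n_uses += dts.size


def estimate_retention(params: ModelParams, seed: int) -> RetentionEstimate:
    """Estimate P_r from K independent temporal sequences.

    Each sequence runs on its own child random stream spawned
    deterministically from ``seed``, so the estimate is reproducible
    bit-for-bit and independent of execution order.
    """
    children = np.random.SeedSequence(seed).spawn(params.n_sequences_K)
    n_losses = 0
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        outcome = run_sequence(params, rng, stream_id=f"seq-{k}")
        n_losses += outcome.lost
    return RetentionEstimate.from_counts(n_losses, params.n_sequences_K)
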