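"""Sampling of use intervals.

Intervals between successive uses of the skill are drawn from the positive
part of a normal distribution with mean ``theta`` and standard deviation
``nu * theta`` — i.e. a normal truncated to (0, inf). Positivity is enforced
by rejection (redraw until positive), never by clipping or taking absolute
values, so the sampled law is exactly the truncated normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ParameterError

__all__ = ["IntervalSequence", "sample_intervals", "required_draw_count"]


@dataclass(frozen=True)
class IntervalSequence:
    """One draw of positive use intervals for a temporal sequence."""

    intervals: np.ndarray  # years, each > 0
    theta: float
    nu: float
    stream_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intervals", np.asarray(self.intervals, dtype=float)
        )
        if self.intervals.size and not (self.intervals > 0).all():
            raise ParameterError("all intervals must be strictly positive")

    def __len__(self) -> int:
        return self.intervals.size


def required_draw_count(horizon_L: float, theta: float) -> int:
    """Number of interval draws that on average doubly covers the horizon.

    Returns ``ceil(2 * L / theta)``: a horizon of ``L`` years contains
    ``L / theta`` intervals on average, so drawing twice that many makes the
    cumulative sum reach ``L`` in all but rare cases (the simulation engine
    extends the sequence when it does not).
    """
    if not horizon_L > 0:
        raise ParameterError(f"horizon_L must be > 0, got {horizon_L!r}")
    if not theta > 0:
        raise ParameterError(f"theta must be > 0, got {theta!r}")
    return max(1, math.ceil(2.0 * horizon_L / theta))


def sample_intervals(
    theta: float,
    nu: float,
    count: int,
    random_stream: np.random.Generator,
    stream_id: str = "",
) -> IntervalSequence:
    """Draw ``count`` independent positive intervals.

    Each draw comes from Normal(theta, (nu*theta)^2) conditioned on being
    strictly positive; non-positive values are rejected and redrawn in
    vectorized batches. With ``nu = 0`` every interval equals ``theta``
    exactly. Consecutive draws are independent.
    """
    if not theta > 0:
        raise ParameterError(f"theta must be > 0, got {theta!r}")
    if nu < 0:
        raise ParameterError(f"nu must be >= 0, got {nu!r}")
    if count < 1:
        raise ParameterError(f"count must be >= 1, got {count!r}")

    if nu == 0:
        values = np.full(count, float(theta))
        return IntervalSequence(values, theta, nu, stream_id)

    sd = nu * theta
    out = np.empty(count, dtype=float)
    filled = 0
    # Acceptance probability is Phi(1/nu) >= 0.69 for nu <= 2, so a modest
    # oversample per batch almost always finishes in one pass.
    while filled < count:
        need = count - filled
        batch = random_stream.normal(theta, sd, size=int(need * 1.6) + 8)
        batch = batch[batch > 0][:need]
        out[filled : filled + batch.size] = batch
        filled += batch.size
    return IntervalSequence(out, theta, nu, stream_id)
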