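"""Model parameters, the exponential expert-decay law, and the maximum
unused-retention time.

The model tracks a group's pool of "experts" — members currently able to
deploy a complex skill (the motivating case is keeping fire by capturing
wildfire embers). Between uses of the skill the expert count decays
exponentially with e-folding time ``tau`` (the *forgetting time*); every use
instantly restores the pool to ``eta_max``. The skill is lost the moment the
continuous expert count drops below ``retention_threshold`` (one person by
default), which happens after

    dt_max = tau * ln(eta_max / threshold)

years without use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ParameterError",
    "ParameterRangeWarning",
    "ModelParams",
    "experts_remaining",
    "expert_count_display",
    "delta_t_max",
    "SWEEP_RANGES",
]


class ParameterError(ValueError):
    """A model parameter violates a mathematical constraint."""


class ParameterRangeWarning(UserWarning):
    """A parameter is valid but outside the canonical sweep ranges."""


#: Canonical sweep bounds (inclusive) used for warnings and CLI defaults:
#: mean use interval theta in years, dimensionless variability nu, maximum
#: expert pool eta_max in individuals, forgetting time tau in years.
SWEEP_RANGES: dict[str, tuple[float, float]] = {
    "theta": (1.0, 20.0),
    "nu": (0.0, 2.0),
    "eta_max": (3.0, 60.0),
    "tau": (1.0, 16.0),
}


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ParameterError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """One point in (theta, nu, eta_max, tau) space plus the fixed horizon.

    Parameters
    ----------
    theta : float
        Mean interval between uses of the skill, years, > 0.
    nu : float
        Dimensionless variability: the interval distribution has standard
        deviation ``nu * theta``. >= 0; ``nu = 0`` makes intervals exact.
    eta_max : float
        Maximum number of experts; the pool resets to this on every use.
        >= 1 individual.
    tau : float
        Forgetting time, years, > 0: after ``tau`` years without use the
        expert count falls to ``eta_max / e`` (about a third).
    horizon_L : float
        Modeled time length in years. Default 1000.
    n_sequences_K : int
        Temporal sequences per Monte-Carlo simulation. Default 111.
    retention_threshold : float
        Minimum expert count for the skill to survive. Default 1 person.
    """

    theta: float
    nu: float
    eta_max: float
    tau: float
    horizon_L: float = 1000.0
    n_sequences_K: int = 111
    retention_threshold: float = 1.0

    def __post_init__(self) -> None:
        _check_positive("theta", self.theta)
        if self.nu < 0:
            raise ParameterError(f"nu must be >= 0, got {self.nu!r}")
        if self.eta_max < 1:
            raise ParameterError(f"eta_max must be >= 1, got {self.eta_max!r}")
        _check_positive("tau", self.tau)
        _check_positive("horizon_L", self.horizon_L)
        if self.n_sequences_K < 1:
            raise ParameterError(
                f"n_sequences_K must be >= 1, got {self.n_sequences_K!r}"
            )
        _check_positive("retention_threshold", self.retention_threshold)
        for name in ("theta", "nu", "eta_max", "tau"):
            lo, hi = SWEEP_RANGES[name]
            value = getattr(self, name)
            if not lo <= value <= hi:
                warnings.warn(
                    f"{name}={value} is outside the canonical sweep range "
                    f"[{lo}, {hi}]; results are extrapolations",
                    ParameterRangeWarning,
                    stacklevel=3,
                )

    @property
    def delta_t_max(self) -> float:
        """Longest unused interval the skill survives, years."""
        return delta_t_max(
            self.tau, self.eta_max, threshold=self.retention_threshold
        )


def experts_remaining(eta_max: float, tau: float, dt: float) -> float:
    """Continuous expert count after ``dt`` years without use.

    Evaluates ``eta_max * exp(-dt / tau)``: strictly decreasing in ``dt``,
    equal to ``eta_max`` at ``dt = 0`` and to ``eta_max / e`` at
    ``dt = tau``. The count is deliberately *not* rounded — the loss rule
    compares it to the retention threshold directly; round only at a
    reporting boundary via :func:`expert_count_display`.
    """
    if eta_max < 1:
        raise ParameterError(f"eta_max must be >= 1, got {eta_max!r}")
    _check_positive("tau", tau)
    if dt < 0:
        raise ParameterError(f"dt must be >= 0, got {dt!r}")
    return eta_max * math.exp(-dt / tau)


def expert_count_display(continuous_count: float) -> int:
    """Whole-person reading of a continuous expert count (floor).

    A continuous count of 7.36 experts is reported as 7 individuals able to
    use the skill.
    """
    if continuous_count < 0:
        raise ParameterError(
            f"expert count must be >= 0, got {continuous_count!r}"
        )
    return math.floor(continuous_count)


def delta_t_max(tau: float, eta_max: float, threshold: float = 1.0) -> float:
    """Maximum time the skill survives without use, ``tau * ln(eta_max)``.

    For a threshold of one person this is the ``dt`` at which
    :func:`experts_remaining` hits exactly 1; a threshold ``m != 1``
    generalizes it to ``tau * ln(eta_max / m)``. Linear in ``tau`` at fixed
    pool size, logarithmic in ``eta_max`` at fixed ``tau``.
    """
    _check_positive("tau", tau)
    if eta_max < 1:
        raise ParameterError(f"eta_max must be >= 1, got {eta_max!r}")
    _check_positive("threshold", threshold)
    return tau * math.log(eta_max / threshold)
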