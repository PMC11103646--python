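"""Parameterization of the generalized drift-diffusion model (DDM).

Evidence accumulates on an axis bounded by two absorbing barriers: 0 (commit to
the low-value stimulus) and ``a`` (commit to the high-value stimulus).  The
process starts at ``z = a/2 + z0``, i.e. offset by ``z0`` evidence units toward
the high barrier, drifts at ``v`` evidence units per second and diffuses with
standard deviation ``s`` per sqrt-second.  Drift is tied to the luminance
contrast of the two offers: ``v = k * (ln lum_high - ln lum_low)``, so a single
free coefficient ``k`` spans conditions.

Three parameters are free — drift coefficient ``k``, boundary separation ``a``
and nondecision time ``t0`` — while noise (1.5), start offset (0.1) and the
lapse mixture (weight 0.2, exponential rate 1/s) are fixed constants of the
model family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "DDMParams",
    "Condition",
    "drift_from_condition",
    "choice_prob_closed_form",
    "NOISE_DEFAULT",
    "START_OFFSET_DEFAULT",
    "LAPSE_MIX_DEFAULT",
    "LAPSE_RATE_DEFAULT",
]

NOISE_DEFAULT = 1.5
START_OFFSET_DEFAULT = 0.1
LAPSE_MIX_DEFAULT = 0.2
LAPSE_RATE_DEFAULT = 1.0


@dataclass(frozen=True)
class DDMParams:
    """Free parameters (k, a, t0) plus the fixed constants of the model."""

    drift_coef: float  # k: evidence/s per unit log-luminance contrast
    boundary_sep: float  # a: evidence units between the two barriers
    nondecision_t: float  # t0: seconds outside the accumulation process
    noise: float = NOISE_DEFAULT  # s: evidence / sqrt(s)
    start_offset: float = START_OFFSET_DEFAULT  # z0: offset toward high barrier
    lapse_mix: float = LAPSE_MIX_DEFAULT  # mixture weight of the lapse process
    lapse_rate: float = LAPSE_RATE_DEFAULT  # 1/s, exponential lapse timing

    def __post_init__(self) -> None:
        if not self.boundary_sep > 0:
            raise ValueError(f"boundary_sep must be > 0, got {self.boundary_sep}")
        if not abs(self.start_offset) < self.boundary_sep / 2:
            raise ValueError(
                f"|start_offset|={abs(self.start_offset)} must be < "
                f"boundary_sep/2={self.boundary_sep / 2}"
            )
        if not self.noise > 0:
            raise ValueError(f"noise must be > 0, got {self.noise}")
        if not 0 <= self.lapse_mix < 1:
            raise ValueError(f"lapse_mix must be in [0,1), got {self.lapse_mix}")
        if not self.nondecision_t >= 0:
            raise ValueError(f"nondecision_t must be >= 0, got {self.nondecision_t}")
        if not self.lapse_rate > 0:
            raise ValueError(f"lapse_rate must be > 0, got {self.lapse_rate}")

    @property
    def start_point(self) -> float:
        """Absolute start position z on the [0, a] evidence axis."""
        return self.boundary_sep / 2 + self.start_offset

    def with_free(self, drift_coef: float, boundary_sep: float,
                  nondecision_t: float) -> "DDMParams":
        return replace(
            self,
            drift_coef=drift_coef,
            boundary_sep=boundary_sep,
            nondecision_t=nondecision_t,
        )


@dataclass(frozen=True)
class Condition:
    """Luminances (LED counts) of the two offers on a dual-offer trial."""

    lum_high: float
    lum_low: float

    def __post_init__(self) -> None:
        if not (self.lum_high > 0 and self.lum_low > 0):
            raise ValueError("luminances must be > 0")


def drift_from_condition(drift_coef: float, cond: Condition) -> float:
    """Drift v = k * (ln lum_high - ln lum_low).

    Positive v pushes the process toward the high-value barrier.  The mapping
    depends only on the luminance ratio, so scaling both offers leaves the
    drift unchanged.
    """
    return drift_coef * (math.log(cond.lum_high) - math.log(cond.lum_low))


def choice_prob_closed_form(params: DDMParams, cond: Condition) -> float:
    """Probability of absorption at the high barrier, before lapse mixing.

    For a Wiener process with drift v and noise s on [0, a] started at z,
    P(hit a before 0) = (1 - exp(-2 v z / s^2)) / (1 - exp(-2 v a / s^2)),
    with the continuous limit z/a at v = 0.
    """
    v = drift_from_condition(params.drift_coef, cond)
    a = params.boundary_sep
    z = params.start_point
    s2 = params.noise**2
    x = 2.0 * v / s2
    if abs(x) * a < 1e-10:
        return z / a
    # expm1 keeps precision when the exponents are small
    return math.expm1(-x * z) / math.expm1(-x * a)
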