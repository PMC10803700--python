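"""Acquisition-duration matching under radioactive decay.

When the same patient is scanned twice after a single injection, the second
acquisition sees a lower activity because the tracer has decayed during the
inter-scan delay.  To compare the two exams at equivalent count statistics,
the second acquisition is extended so that its *expected* total counts equal
those of the first.  With a mono-exponential decay of rate ``lam``
(min^-1), the expected counts collected over ``[start, start + duration]``
are proportional to the integral of ``exp(-lam * t)``, which gives a closed
form for both the count integral and the matched duration.

F-18 half-life: 109.77 min, so ``lam = ln 2 / 109.77 ~ 6.31e-3 min^-1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InfeasibleError, ValidationError

#: F-18 half-life in minutes.
F18_HALF_LIFE_MIN = 109.77

#: F-18 decay constant in min^-1.
F18_LAMBDA = math.log(2.0) / F18_HALF_LIFE_MIN


def expected_counts(start_min: float, duration_min: float, lam: float) -> float:
    """Expected counts over ``[start, start + duration]`` for unit initial activity.

    Returns ``(exp(-lam*start) - exp(-lam*(start+duration))) / lam``; in the
    ``lam -> 0`` limit this tends to ``duration``.
    """
    if lam <= 0:
        raise ValidationError("decay constant must be > 0")
    if duration_min <= 0:
        raise ValidationError("duration must be > 0")
    # -expm1 keeps precision for lam*duration << 1
    return math.exp(-lam * start_min) * (-math.expm1(-lam * duration_min)) / lam


def solve_duration(t1_min: float, delay_min: float, lam: float = F18_LAMBDA) -> float:
    """Duration of the second acquisition matching the first's expected counts.

    Solves ``expected_counts(delay, t2) == expected_counts(0, t1)`` for t2:

        t2 = -ln(1 - exp(lam*delay) * (1 - exp(-lam*t1))) / lam

    Raises
    ------
    InfeasibleError
        When the decay is so deep that no finite duration can recover the
        first exam's counts, i.e. ``exp(lam*delay)*(1-exp(-lam*t1)) >= 1``.
    """
    if lam <= 0:
        raise ValidationError("decay constant must be > 0")
    if t1_min <= 0:
        raise ValidationError("first-exam duration must be > 0")
    if delay_min < 0:
        raise ValidationError("delay must be >= 0")
    g = math.exp(lam * delay_min) * (-math.expm1(-lam * t1_min))
    if g >= 1.0:
        max_fraction = math.exp(-lam * delay_min) / (lam * expected_counts(0.0, t1_min, lam))
        raise InfeasibleError(
            "count matching infeasible: an infinite second acquisition would "
            f"collect at most {max_fraction:.4f} of the first exam's counts"
        )
    return -math.log1p(-g) / lam


@dataclass
class AcquisitionPlan:
    """A solved scan-rescan acquisition plan (single bed position)."""

    t1_min: float
    delay_min: float
    lam: float
    t2_min: float

    def to_dict(self) -> dict:
        return {
            "t1_min": self.t1_min,
            "delay_min": self.delay_min,
            "lambda_per_min": self.lam,
            "t2_min": self.t2_min,
        }


def plan_acquisition(
    t1_min: float, delay_min: float, half_life_min: float = F18_HALF_LIFE_MIN
) -> AcquisitionPlan:
    """Solve the matched plan for a given half-life (default F-18)."""
    lam = math.log(2.0) / half_life_min
    t2 = solve_duration(t1_min, delay_min, lam)
    return AcquisitionPlan(t1_min=t1_min, delay_min=delay_min, lam=lam, t2_min=t2)


def simulate_matched_counts(
    t1_min: float,
    delay_min: float,
    lam: float = F18_LAMBDA,
    expected_total: float = 1e6,
    n_realizations: int = 100,
    seed: int = 0,
):
    """Poisson realizations of the matched scan-rescan count totals.

    Scales initial activity so that each exam's expected counts equal
    ``expected_total``, draws paired Poisson totals and returns the array of
    signed relative differences ``(N2 - N1) / N1``.
    """
    import numpy as np

    t2 = solve_duration(t1_min, delay_min, lam)
    mu1 = expected_counts(0.0, t1_min, lam)
    mu2 = expected_counts(delay_min, t2, lam)
    scale = expected_total / mu1
    rng = np.random.default_rng(seed)
    n1 = rng.poisson(mu1 * scale, size=n_realizations).astype(float)
    n2 = rng.poisson(mu2 * scale, size=n_realizations).astype(float)
    return (n2 - n1) / n1
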