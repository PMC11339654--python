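"""Deterministic conversions between genetic and calendar time, and
between homozygous-by-descent (HBD) rate classes and ancestor generations.

An HBD class with rate ``Rc`` has exponentially distributed segment lengths
with expectation 1/Rc Morgans and corresponds to a group of ancestors living
about Rc/2 generations in the past.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TimeScale:
    """Calendar anchoring of a generation clock.

    generation_time : years per generation
    reference_year  : mean birth year of the sampled individuals
    founding_year   : calendar year of population establishment
    """

    generation_time: float = 6.0
    reference_year: int = 1992
    founding_year: int = 1871

    def __post_init__(self):
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")
        if self.founding_year > self.reference_year:
            raise ValueError("founding_year must not exceed reference_year")


def generations_to_year(t_gen: float, scale: TimeScale = TimeScale()) -> int:
    """Calendar year lying ``t_gen`` generations before the reference year."""
    if t_gen < 0:
        raise ValueError("t_gen must be non-negative")
    return round(scale.reference_year - t_gen * scale.generation_time)


def implied_generation_time(scale: TimeScale, n_generations: float) -> float:
    """Years per generation implied by spanning founding→reference in
    ``n_generations`` generations."""
    if n_generations <= 0:
        raise ValueError("n_generations must be positive")
    return (scale.reference_year - scale.founding_year) / n_generations


def hbd_class_properties(rc: float) -> tuple[float, float]:
    """(expected segment length in Morgans, ancestor generations) for an
    HBD class of rate ``rc``."""
    if rc <= 0:
        raise ValueError("Rc must be positive")
    return 1.0 / rc, rc / 2.0


def hbd_rate_grid(min_rate: int = 2, max_rate: int = 8192) -> list[int]:
    """Doubling grid of HBD class rates from ``min_rate`` to ``max_rate``
    inclusive; both bounds must be powers of two."""
    for v, name in ((min_rate, "min_rate"), (max_rate, "max_rate")):
        if v < 1 or (v & (v - 1)) != 0:
            raise ValueError(f"{name} must be a power of two, got {v}")
    if max_rate < min_rate:
        raise ValueError("max_rate must be >= min_rate")
    rates = []
    r = min_rate
    while r <= max_rate:
        rates.append(r)
        r *= 2
    return rates
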