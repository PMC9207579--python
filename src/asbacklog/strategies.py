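"""Intervention strategies and their surplus-capacity arithmetic.

Two levers create capacity above the pre-pandemic baseline:

1. a *general* capacity increase (extra lists, more procedures per list),
   a fraction ``c`` of throughput;
2. *conversion* of a fraction ``p`` of SAVR cases to the faster TAVI
   procedure at a time-equivalence ratio ``a:b`` ("b TAVI fit in the
   operating time of a SAVR"), freeing ``b/a - 1`` slots per converted case.

Combined, the general increase applies to the post-conversion mix:

    Te = conv + c * (rS0 + rT0 + conv),   conv = p * rS0 * (b/a - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

from .model_core import PopulationParams

__all__ = [
    "RatioError",
    "CapExceededWarning",
    "ConversionRatio",
    "Strategy",
    "conversion_surplus",
    "total_surplus",
    "per_day",
]

#: soft policy caps: at most 50% of SAVR cases convertible, at most 50%
#: extra capacity by other means in the short term.
DEFAULT_CAP = 0.5


class RatioError(ValueError):
    """Conversion ratio frees no surplus (b <= a)."""


class CapExceededWarning(UserWarning):
    """A strategy exceeds the short-term policy caps (p or c > 0.5)."""


@dataclass(frozen=True)
class ConversionRatio:
    """Time-equivalence ratio a:b — b TAVI in the time of a SAVR.

    The default 2:3 reflects typical operating times (SAVR 2-4 h, TAVI
    1-2 h). Sensitivity ratios considered: 3:4, 2:4 and 3:5 (SAVR:TAVI).
    The slot gain ``b/a - 1`` is kept as an exact rational.
    """

    savr_slots: int = 2
    tavi_slots: int = 3

    def __post_init__(self) -> None:
        if self.savr_slots < 1:
            raise ValueError("savr_slots must be >= 1")
        if self.tavi_slots <= self.savr_slots:
            raise RatioError(
                f"ratio {self.savr_slots}:{self.tavi_slots} frees no surplus "
                "(need tavi_slots > savr_slots)"
            )

    @property
    def gain(self) -> Fraction:
        """Extra slots freed per converted case, exact: b/a - 1."""
        return Fraction(self.tavi_slots, self.savr_slots) - 1

    @classmethod
    def parse(cls, text: str) -> "ConversionRatio":
        """Parse 'a:b' notation, e.g. '2:3'."""
        try:
            a, b = (int(part) for part in text.split(":"))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"cannot parse conversion ratio {text!r}") from exc
        return cls(a, b)

    def __str__(self) -> str:
        return f"{self.savr_slots}:{self.tavi_slots}"


@dataclass(frozen=True)
class Strategy:
    """An intervention: general capacity increase + SAVR->TAVI conversion.

    ``capacity_increase`` and ``conversion_fraction`` are fractions (0.2,
    not 20). Values above the 0.5 short-term caps are allowed (doubling
    capacity is an explored scenario) but emit :class:`CapExceededWarning`
    unless ``allow_above_cap`` is set.
    """

    capacity_increase: float = 0.0
    conversion_fraction: float = 0.0
    ratio: ConversionRatio = field(default_factory=ConversionRatio)
    allow_above_cap: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_fraction <= 1.0:
            raise ValueError("conversion_fraction must lie in [0, 1]")
        if self.capacity_increase < 0.0:
            raise ValueError("capacity_increase must be nonnegative")
        if not self.allow_above_cap and (
            self.capacity_increase > DEFAULT_CAP
            or self.conversion_fraction > DEFAULT_CAP
        ):
            warnings.warn(
                "strategy exceeds the short-term 50% caps on conversion/"
                "capacity; pass allow_above_cap=True to silence",
                CapExceededWarning,
                stacklevel=3,
            )


def conversion_surplus(
    params: PopulationParams, p: float, ratio: ConversionRatio | None = None
) -> float:
    """Surplus (procedures/year) from converting a fraction ``p`` of SAVR.

    Converted patients still occupy one treatment slot each; the surplus is
    the extra slots freed by the faster procedure: ``p * rS0 * (b/a - 1)``.
    """
    if ratio is None:
        ratio = ConversionRatio()
    if not 0.0 <= p <= 1.0:
        raise ValueError("conversion fraction p must lie in [0, 1]")
    if ratio.gain <= 0:
        raise RatioError(f"ratio {ratio} frees no surplus")
    return p * params.rS0 * float(ratio.gain)


def total_surplus(params: PopulationParams, strategy: Strategy) -> float:
    """Total surplus capacity Te (procedures/year) of a combined strategy.

    The general increase applies to the post-conversion throughput:
    ``Te = conv + c * (rS0 + rT0 + conv)``.
    """
    p = strategy.conversion_fraction
    conv = (
        conversion_surplus(params, p, strategy.ratio) if p > 0 else 0.0
    )
    return conv + strategy.capacity_increase * (params.baseline_throughput + conv)


def per_day(Te_per_year: float, params: PopulationParams) -> float:
    """Convert procedures/year to procedures/day (365-day year)."""
    return Te_per_year / params.days_per_year
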