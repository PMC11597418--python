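"""Crop-management schedule: fertilization events, organic-matter inputs
(green manure, straw) and the irrigation/drainage policy that together define
a treatment."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .water import IrrigationPolicy

__all__ = [
    "FertEvent",
    "OrganicInput",
    "ManagementSchedule",
    "green_manure",
    "straw_return",
    "split_fertilizer",
]

FERT_KINDS = ("basal", "tillering", "booting")


@dataclass(frozen=True)
class FertEvent:
    """One mineral-N application.

    ``f_surf`` is the fraction of applied N that enters the surface-water
    dissolved pool on the day of application (broadcast urea is assumed
    hydrolyzed to NH4 within the daily step); the remainder goes to the soil
    N store outside the surface pool.
    """

    day: int
    n_amount: float
    kind: str = "basal"
    f_surf: float = 0.3

    def __post_init__(self) -> None:
        if self.n_amount < 0:
            raise ValueError("n_amount must be >= 0")
        if not (0.0 <= self.f_surf <= 1.0):
            raise ValueError("f_surf must lie in [0, 1]")
        if self.kind not in FERT_KINDS:
            raise ValueError(f"kind must be one of {FERT_KINDS}")


@dataclass(frozen=True)
class OrganicInput:
    """Incorporated organic material (green manure or straw).

    N release is first order: day t after incorporation mineralizes
    ``n_content · k_min · exp(−k_min t)`` of which fraction ``f_surf`` reaches
    the surface-water pools directly, split ``nh4_frac`` : (1 − nh4_frac)
    between NH4 and DON, and fraction ``f_soil`` joins the exchangeable soil
    mineral-N pool (the remainder is stabilized into soil organic matter).
    ``f_pn`` of the N content enters the particulate pool as a pulse at
    incorporation.  ``k_imm`` is a first-order microbial-immobilization rate
    acting on surface NH4 while the residue decomposes (high-C:N straw); it
    decays with the residue as ``k_imm · exp(−k_min t)``.
    """

    day: int
    n_content: float
    kind: str = "green_manure"
    k_min: float = 0.05
    f_surf: float = 0.1
    nh4_frac: float = 0.6
    f_pn: float = 0.02
    k_imm: float = 0.0
    f_soil: float = 0.6

    def __post_init__(self) -> None:
        if self.n_content < 0 or self.k_min < 0 or self.k_imm < 0:
            raise ValueError("n_content, k_min and k_imm must be >= 0")
        if not (
            0 <= self.f_surf <= 1 and 0 <= self.nh4_frac <= 1
            and 0 <= self.f_pn <= 1 and 0 <= self.f_soil <= 1
        ):
            raise ValueError("fractions must lie in [0, 1]")
        if self.f_surf + self.f_soil > 1:
            raise ValueError("f_surf + f_soil must not exceed 1")
        if self.kind not in ("green_manure", "straw"):
            raise ValueError("kind must be 'green_manure' or 'straw'")


def green_manure(day: int = 0, n_content: float = 60.0, **kwargs) -> OrganicInput:
    """Chinese-milk-vetch incorporation at full flowering: fast release.

    The residue is plowed into the soil before flooding, so only a small
    fraction of each day's mineralized N reaches the surface water."""
    kwargs.setdefault("k_min", 0.05)
    kwargs.setdefault("f_surf", 0.05)
    return OrganicInput(day=day, n_content=n_content, kind="green_manure", **kwargs)


def straw_return(day: int = 0, n_content: float = 30.0, **kwargs) -> OrganicInput:
    """Rice-straw return: slow release, net early-season NH4 immobilization
    (high C:N residue)."""
    kwargs.setdefault("k_min", 0.01)
    kwargs.setdefault("k_imm", 0.08)
    kwargs.setdefault("f_surf", 0.03)
    kwargs.setdefault("f_pn", 0.01)
    kwargs.setdefault("f_soil", 0.3)
    return OrganicInput(day=day, n_content=n_content, kind="straw", **kwargs)


def split_fertilizer(
    total_n: float,
    ratios: tuple[float, ...],
    days: tuple[int, ...],
    f_surf: float = 0.3,
) -> tuple[FertEvent, ...]:
    """Split a seasonal N rate across basal/tillering/booting applications.

    ``ratios`` like (6, 4) or (11, 7, 2) are normalized; ``days`` are days
    after transplanting for each split.
    """
    if len(ratios) != len(days) or not 1 <= len(ratios) <= 3:
        raise ValueError("need 1-3 matching ratios and days")
    total_ratio = sum(ratios)
    return tuple(
        FertEvent(day=d, n_amount=total_n * r / total_ratio, kind=FERT_KINDS[i], f_surf=f_surf)
        for i, (r, d) in enumerate(zip(ratios, days))
    )


@dataclass(frozen=True)
class ManagementSchedule:
    """Everything that defines a treatment on a site: season dates, mineral
    fertilization, organic inputs, and the water-management policy."""

    transplant: str
    harvest: str
    fert_events: tuple[FertEvent, ...] = ()
    organic_inputs: tuple[OrganicInput, ...] = ()
    policy: IrrigationPolicy = field(default_factory=IrrigationPolicy)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fert_events", tuple(self.fert_events))
        object.__setattr__(self, "organic_inputs", tuple(self.organic_inputs))

    @property
    def total_fert_n(self) -> float:
        return sum(e.n_amount for e in self.fert_events)

    def with_fert_fraction(self, fraction: float) -> "ManagementSchedule":
        events = tuple(
            dataclasses.replace(e, n_amount=e.n_amount * fraction) for e in self.fert_events
        )
        return dataclasses.replace(self, fert_events=events)

    def with_organics(self, *inputs: OrganicInput) -> "ManagementSchedule":
        return dataclasses.replace(
            self, organic_inputs=self.organic_inputs + tuple(inputs)
        )

    def with_f_surf(self, f_surf: float) -> "ManagementSchedule":
        events = tuple(dataclasses.replace(e, f_surf=f_surf) for e in self.fert_events)
        return dataclasses.replace(self, fert_events=events)
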