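"""Deterministic dietary risk metrics: EDI, MOE, HQ, HI.

Core relations (all inputs non-negative):

    EDI  = C_content x C_food / BW      [mg/kg bw/day]
    MOE  = HBGV / EDI                   [dimensionless, chronic]
    HQ   = EDI / ARfD                   [dimensionless, acute]
    HI   = sum of HQ over commodities
    sum-MOE = HBGV / sum-EDI            [cumulative chronic]

where C_content is the residue concentration (mg/kg), C_food the
consumption (kg/day or kg/occasion), BW the body weight (kg), HBGV a
health-based guidance value and ARfD the acute reference dose (both
mg/kg bw/day).

Chronic concern is read off the MOE: below ``moe_concern`` (default
300) signals a potential health concern, between ``moe_concern`` and
``moe_caution`` (default 1000) a possible concern, above that none.
Acute concern uses HQ/HI against 1; the boundary value 1 itself is
classified as a concern (conservative reading of "below 1 means no
concern").
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class Classification(str, enum.Enum):
    NO_CONCERN = "no_concern"
    POSSIBLE_CONCERN = "possible_concern"
    CONCERN = "concern"


#: Sentinel for MOE at zero exposure (reported as "unbounded", never inf).
UNBOUNDED = "unbounded"


@dataclass(frozen=True)
class ReferenceValues:
    """Toxicological reference values and population body weight.

    Defaults are the chlorpyrifos values used for the Armenian adult
    population: the EFSA developmental-neurotoxicity LOAEL of
    0.3 mg/kg bw/day as chronic HBGV; the artificially low ARfD of
    1e-4 mg/kg bw/day adopted in 2020 (the pre-2020 ARfD of 0.005 is
    kept as a scenario value); MOE concern thresholds 300/1000; mean
    adult body weight 71.5 kg.
    """

    hbgv_loael: float = 0.3
    arfd_low: float = 1e-4
    arfd_2014: float = 0.005
    moe_concern: float = 300.0
    moe_caution: float = 1000.0
    hq_threshold: float = 1.0
    bw: float = 71.5

    def __post_init__(self) -> None:
        for name in (
            "hbgv_loael", "arfd_low", "arfd_2014",
            "moe_concern", "moe_caution", "hq_threshold", "bw",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.moe_concern >= self.moe_caution:
            raise ValueError("moe_concern must be below moe_caution")

    def arfd(self, basis: str = "low") -> float:
        if basis == "low":
            return self.arfd_low
        if basis == "2014":
            return self.arfd_2014
        raise ValueError(f"unknown ARfD basis {basis!r}; use 'low' or '2014'")


def edi(c_content: float, c_food: float, bw: float) -> float:
    """Estimated daily intake, mg/kg bw/day."""
    if bw <= 0:
        raise ValueError("body weight must be positive")
    if c_content < 0 or c_food < 0:
        raise ValueError("concentration and consumption must be non-negative")
    return c_content * c_food / bw


def cumulative_edi(edis: Sequence[float] | np.ndarray) -> float:
    """Sum of per-commodity EDIs (same horizon and reference basis)."""
    arr = np.asarray(edis, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("EDIs must be non-negative")
    return float(arr.sum())


def moe(edi_value: float, hbgv: float) -> float | str:
    """Margin of exposure HBGV/EDI; ``UNBOUNDED`` at zero exposure."""
    if hbgv <= 0:
        raise ValueError("HBGV must be positive")
    if edi_value < 0:
        raise ValueError("EDI must be non-negative")
    if edi_value == 0:
        return UNBOUNDED
    return hbgv / edi_value


def hq(edi_value: float, arfd: float) -> float:
    """Hazard quotient EDI/ARfD."""
    if arfd <= 0:
        raise ValueError("ARfD must be positive")
    if edi_value < 0:
        raise ValueError("EDI must be non-negative")
    return edi_value / arfd


def hazard_index(hqs: Iterable[float]) -> float:
    """Hazard index: sum of hazard quotients (0 for an empty set)."""
    total = 0.0
    for q in hqs:
        if q < 0:
            raise ValueError("HQ values must be non-negative")
        total += q
    return total


def cumulative_moe(edis: Sequence[float], hbgv: float) -> float | str:
    """HBGV divided by the summed EDI.

    Satisfies 1/sum-MOE = sum of 1/MOE_i, hence sum-MOE <= min MOE_i.
    """
    return moe(cumulative_edi(edis), hbgv)


def classify_chronic(
    moe_value: float | str, refs: ReferenceValues | None = None
) -> Classification:
    """Chronic concern class from an MOE (unbounded => no concern)."""
    refs = refs or ReferenceValues()
    if moe_value == UNBOUNDED:
        return Classification.NO_CONCERN
    m = float(moe_value)  # type: ignore[arg-type]
    if m < refs.moe_concern:
        return Classification.CONCERN
    if m <= refs.moe_caution:
        return Classification.POSSIBLE_CONCERN
    return Classification.NO_CONCERN


def classify_acute(
    hq_or_hi: float, refs: ReferenceValues | None = None
) -> Classification:
    """Acute concern class from an HQ or HI; the boundary value itself
    counts as a concern."""
    refs = refs or ReferenceValues()
    if hq_or_hi < 0:
        raise ValueError("HQ/HI must be non-negative")
    if hq_or_hi >= refs.hq_threshold:
        return Classification.CONCERN
    return Classification.NO_CONCERN


@dataclass(frozen=True)
class ExposureEstimate:
    """A mean EDI with its range, for one commodity/horizon/scope."""

    commodity: str  # commodity label or "combined"
    horizon: str  # "chronic" | "acute"
    scope: str  # "all_consumers", "group 1", ...
    edi: float
    edi_min: float = math.nan
    edi_max: float = math.nan


@dataclass(frozen=True)
class RiskMetrics:
    """Risk metrics derived from one exposure estimate."""

    exposure: ExposureEstimate
    moe: float | str | None = None
    hq: float | None = None
    classification: Classification | None = None


def assess_chronic(
    exposure: ExposureEstimate, refs: ReferenceValues | None = None
) -> RiskMetrics:
    refs = refs or ReferenceValues()
    m = moe(exposure.edi, refs.hbgv_loael)
    return RiskMetrics(exposure=exposure, moe=m, classification=classify_chronic(m, refs))


def assess_acute(
    exposure: ExposureEstimate,
    refs: ReferenceValues | None = None,
    arfd_basis: str = "low",
) -> RiskMetrics:
    refs = refs or ReferenceValues()
    q = hq(exposure.edi, refs.arfd(arfd_basis))
    return RiskMetrics(exposure=exposure, hq=q, classification=classify_acute(q, refs))
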