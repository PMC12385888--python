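"""Summaries of left-censored pesticide residue surveys.

A residue survey is a set of composite samples analysed for one pesticide
in one commodity.  Each sample is either *detected* (a numeric
concentration in mg/kg) or *non-detected* (left-censored: known only to
lie below the limit of detection).  Censored samples are handled by
substitution, the convention used in regulatory dietary exposure work:

========  ==========================================
rule      substituted value for a non-detected sample
========  ==========================================
LB        0                 (lower bound)
MB        LOD / 2           (middle bound)
UB        LOD               (upper bound)
========  ==========================================

A fourth rule, ``detected_only``, ignores censored samples entirely and
summarizes the detected concentrations alone; it is the default because
exposure here is driven by the mean of the *detected* residue levels.
"""

from __future__ import annotations

import enum
import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence


class CensoringRule(str, enum.Enum):
    """How to treat samples below the limit of detection."""

    DETECTED_ONLY = "detected_only"
    LB = "LB"
    MB = "MB"
    UB = "UB"

    @classmethod
    def coerce(cls, rule: "CensoringRule | str") -> "CensoringRule":
        if isinstance(rule, cls):
            return rule
        try:
            return cls(rule)
        except ValueError:
            valid = ", ".join(r.value for r in cls)
            raise ConfigurationError(
                f"unknown censoring rule {rule!r}; expected one of: {valid}"
            ) from None


class ConfigurationError(ValueError):
    """Raised for invalid run configuration (unknown rule, bad reference value...)."""


class NoDetectedValuesError(ValueError):
    """Raised when a detected-only summary is requested but nothing was detected."""


@dataclass(frozen=True)
class ResidueSample:
    """One composite sample analysed for one pesticide.

    Parameters
    ----------
    commodity, analyte
        Labels, e.g. ``"tomato"``, ``"chlorpyrifos"``.
    detected
        Whether the analyte was found above the limit of detection.
    value
        Measured concentration in mg/kg; present iff ``detected``.
    lod, loq
        Limits of detection and quantification of the analytical method,
        mg/kg.  Must satisfy ``lod < loq``.
    """

    commodity: str
    analyte: str
    detected: bool
    value: float | None
    lod: float
    loq: float

    def __post_init__(self) -> None:
        if not (0 <= self.lod < self.loq):
            raise ValueError(
                f"require 0 <= LOD < LOQ, got lod={self.lod}, loq={self.loq}"
            )
        if self.detected:
            if self.value is None or self.value < 0:
                raise ValueError("a detected sample needs a non-negative value")
        elif self.value is not None:
            raise ValueError("a non-detected sample must not carry a numeric value")


@dataclass(frozen=True)
class ResidueSummary:
    """Concentration statistics for one (commodity, analyte) survey."""

    commodity: str
    analyte: str
    n_samples: int
    n_detected: int
    detection_fraction: float
    mean: float
    sd: float
    min: float
    max: float
    censoring_rule: CensoringRule


def substitute_censored(sample: ResidueSample, rule: CensoringRule | str) -> float:
    """Concentration to use for *sample* under a substitution *rule*.

    Detected samples pass through unchanged; non-detected samples return
    0, LOD/2 or LOD for LB, MB, UB respectively.  ``detected_only`` is
    not a substitution and is rejected here.
    """
    rule = CensoringRule.coerce(rule)
    if sample.detected:
        return float(sample.value)  # type: ignore[arg-type]
    if rule is CensoringRule.LB:
        return 0.0
    if rule is CensoringRule.MB:
        return sample.lod / 2.0
    if rule is CensoringRule.UB:
        return sample.lod
    raise ConfigurationError(
        "detected_only is not a substitution rule; use LB, MB or UB"
    )


def summarize_residues(
    samples: Iterable[ResidueSample],
    rule: CensoringRule | str = CensoringRule.DETECTED_ONLY,
    *,
    sample_sd: bool = True,
) -> ResidueSummary:
    """Summarize a single-commodity residue survey under a censoring rule.

    Under ``detected_only`` the mean/sd/min/max cover detected values
    alone; under LB/MB/UB they cover all samples after substitution.
    ``sample_sd`` selects the n-1 (default) versus n denominator.

    Raises
    ------
    NoDetectedValuesError
        If ``rule="detected_only"`` and the survey has no detections.
    ValueError
        On an empty survey or a mixed commodity/analyte set.
    """
    rule = CensoringRule.coerce(rule)
    samples = list(samples)
    if not samples:
        raise ValueError("cannot summarize an empty sample set")
    keys = {(s.commodity, s.analyte) for s in samples}
    if len(keys) > 1:
        raise ValueError(f"expected a single (commodity, analyte) survey, got {sorted(keys)}")
    (commodity, analyte) = keys.pop()

    n = len(samples)
    n_det = sum(s.detected for s in samples)
    if rule is CensoringRule.DETECTED_ONLY:
        values = [float(s.value) for s in samples if s.detected]  # type: ignore[arg-type]
        if not values:
            raise NoDetectedValuesError(
                f"no detected values for {commodity}/{analyte}; "
                "use LB/MB/UB or supply detections"
            )
    else:
        values = [substitute_censored(s, rule) for s in samples]

    mean = statistics.fmean(values)
    if len(values) == 1:
        sd = 0.0
    elif sample_sd:
        sd = statistics.stdev(values)
    else:
        sd = statistics.pstdev(values)
    return ResidueSummary(
        commodity=commodity,
        analyte=analyte,
        n_samples=n,
        n_detected=n_det,
        detection_fraction=n_det / n,
        mean=mean,
        sd=sd,
        min=min(values),
        max=max(values),
        censoring_rule=rule,
    )


def summarize_by_group(
    samples: Sequence[ResidueSample],
    rule: CensoringRule | str = CensoringRule.DETECTED_ONLY,
) -> list[ResidueSummary]:
    """Summarize a multi-commodity table per (commodity, analyte) group."""
    groups: dict[tuple[str, str], list[ResidueSample]] = {}
    for s in samples:
        groups.setdefault((s.commodity, s.analyte), []).append(s)
    return [summarize_residues(g, rule) for _, g in sorted(groups.items())]
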