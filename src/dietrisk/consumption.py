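"""Food-frequency-questionnaire (FFQ) intake modelling.

An FFQ records, per respondent and commodity, a consumption frequency
category (e.g. "2-4 times per week") and a typical portion size in
grams.  Two intake quantities are derived:

* chronic intake, kg/day  = events/day x portion/1000 — the long-run
  average daily consumption used for chronic exposure;
* acute intake, kg/occasion = portion/1000 — the amount eaten in one
  sitting, used for acute exposure.

Frequency categories are converted to events/day through a mapping
table that is *data, not code*: the shipped default uses the
midpoint-of-range convention (e.g. "2-4 times per week" -> 3/7) and an
average month of 30.44 days, and can be replaced or extended by the
caller.  The "other" category has no defensible default rate and must
be supplied explicitly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

DAYS_PER_MONTH = 30.44  # 365.25 / 12
DAYS_PER_WEEK = 7.0

#: Default frequency-category -> events/day mapping (midpoint convention).
DEFAULT_FREQUENCY_MAP: dict[str, float] = {
    "no consumption": 0.0,
    "2-3 times per day": 2.5,
    "twice a day": 2.0,
    "once a day": 1.0,
    "5-6 times per week": 5.5 / DAYS_PER_WEEK,
    "2-4 times per week": 3.0 / DAYS_PER_WEEK,
    "once a week": 1.0 / DAYS_PER_WEEK,
    "2-3 times per month": 2.5 / DAYS_PER_MONTH,
    "once a month": 1.0 / DAYS_PER_MONTH,
}


class UnknownFrequencyCategory(KeyError):
    """Raised when a frequency category is absent from the mapping table."""


def frequency_to_events_per_day(
    category: str, mapping: Mapping[str, float] | None = None
) -> float:
    """Convert a frequency category label to an events/day rate.

    "other" (or any unmapped label) raises, listing the known
    categories, because open-ended answers need an explicit rate.
    """
    table = DEFAULT_FREQUENCY_MAP if mapping is None else mapping
    # En-dash variants normalised so CSV sources with either dash work.
    key = category.strip().replace("–", "-").replace("—", "-").lower()
    lowered = {k.lower(): v for k, v in table.items()}
    if key not in lowered:
        raise UnknownFrequencyCategory(
            f"frequency category {category!r} not in mapping; known: "
            + ", ".join(sorted(table))
        )
    rate = float(lowered[key])
    if rate < 0:
        raise ValueError(f"negative events/day for {category!r}")
    return rate


@dataclass(frozen=True)
class ConsumptionRecord:
    """One respondent's FFQ answer for one commodity.

    ``chronic_intake_kg_day`` and ``acute_intake_kg`` are derived by
    :func:`derive_intakes`; demographics are carried through for
    reporting but never enter any exposure computation.
    """

    respondent_id: str
    commodity: str
    frequency_category: str
    portion_g: float | None
    events_per_day: float | None = None
    chronic_intake_kg_day: float | None = None
    acute_intake_kg: float | None = None
    demographics: Mapping[str, str] = field(default_factory=dict)

    @property
    def is_consumer(self) -> bool:
        return (self.events_per_day or 0.0) > 0.0


class MissingPortionError(ValueError):
    """A consuming respondent reported no portion size."""


def derive_intakes(
    record: ConsumptionRecord, mapping: Mapping[str, float] | None = None
) -> ConsumptionRecord:
    """Fill events/day and the chronic/acute intakes of one record.

    chronic = events/day x portion_g / 1000 (kg/day);
    acute   = portion_g / 1000 (kg per occasion).
    Non-consumers get zero for both.  A consuming respondent without a
    portion size raises :class:`MissingPortionError` so the caller can
    flag and exclude the record.
    """
    rate = record.events_per_day
    if rate is None:
        rate = frequency_to_events_per_day(record.frequency_category, mapping)
    if rate == 0.0:
        return replace(
            record, events_per_day=0.0, chronic_intake_kg_day=0.0, acute_intake_kg=0.0
        )
    if record.portion_g is None:
        raise MissingPortionError(
            f"respondent {record.respondent_id}: consuming record without portion size"
        )
    if record.portion_g < 0:
        raise ValueError("portion_g must be non-negative")
    acute = record.portion_g / 1000.0
    return replace(
        record,
        events_per_day=rate,
        chronic_intake_kg_day=rate * acute,
        acute_intake_kg=acute,
    )


def derive_all_intakes(
    records: Iterable[ConsumptionRecord],
    mapping: Mapping[str, float] | None = None,
) -> tuple[list[ConsumptionRecord], list[ConsumptionRecord]]:
    """Derive intakes for many records; returns (derived, excluded).

    Records that fail (missing portion for a consumer) are excluded and
    returned separately rather than aborting the run.
    """
    out: list[ConsumptionRecord] = []
    excluded: list[ConsumptionRecord] = []
    for rec in records:
        try:
            out.append(derive_intakes(rec, mapping))
        except MissingPortionError:
            excluded.append(rec)
    return out, excluded


def trim_outliers(
    intakes: Sequence[float] | np.ndarray, upper_percentile: float = 0.05
) -> tuple[np.ndarray, int]:
    """Drop intakes strictly above the (1 - upper_percentile) quantile.

    One-sided upper trim: intake distributions are right-skewed, so the
    exclusion targets implausibly large values only.  Quantiles use
    linear interpolation (type 7).  Returns (retained values in input
    order, number removed).
    """
    if not 0 <= upper_percentile < 1:
        raise ValueError("upper_percentile must be in [0, 1)")
    x = np.asarray(intakes, dtype=float)
    if x.size == 0:
        raise ValueError("cannot trim an empty intake vector")
    if upper_percentile == 0:
        return x.copy(), 0
    cutoff = np.quantile(x, 1.0 - upper_percentile)  # type 7
    keep = x <= cutoff
    return x[keep], int((~keep).sum())


@dataclass(frozen=True)
class BinningResult:
    """Assignment of consumers to ordered consumption groups.

    ``group_index`` is 1-based per input value; ``boundaries[k]`` is the
    (lower, upper) intake interval of group k+1, lower-inclusive and
    upper-exclusive except the last group which is closed above;
    ``fractions`` sum to 1 over groups.
    """

    group_index: np.ndarray
    boundaries: list[tuple[float, float]]
    fractions: np.ndarray

    @property
    def k(self) -> int:
        return len(self.boundaries)


def bin_consumers(
    intakes: Sequence[float] | np.ndarray,
    strategy: str = "equal_count",
    k: int = 5,
    cutpoints: Sequence[float] | None = None,
) -> BinningResult:
    """Partition consumer intakes into k ordered consumption groups.

    Strategies
    ----------
    equal_count
        Cut at the j/k empirical quantiles (type 7), approximating
        equal group sizes.
    equal_width
        k equal-width intervals over [min, max].
    explicit_cutpoints
        Caller-supplied strictly increasing inner cutpoints
        (k = len(cutpoints) + 1).  Values tied with a cutpoint fall in
        the interval whose lower bound they equal.
    """
    x = np.asarray(intakes, dtype=float)
    if x.size == 0:
        raise ValueError("no consumer intakes to bin")
    if np.any(x <= 0):
        raise ValueError("bin_consumers expects consumers only (all intakes > 0)")

    if strategy == "explicit_cutpoints":
        if cutpoints is None:
            raise ValueError("explicit_cutpoints strategy needs cutpoints")
        cuts = np.asarray(cutpoints, dtype=float)
        if np.any(np.diff(cuts) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
    elif strategy == "equal_count":
        if k < 2:
            raise ValueError("k must be >= 2")
        qs = np.quantile(x, np.arange(1, k) / k)
        cuts = np.unique(qs)
    elif strategy == "equal_width":
        if k < 2:
            raise ValueError("k must be >= 2")
        cuts = np.linspace(x.min(), x.max(), k + 1)[1:-1]
    else:
        raise ValueError(f"unknown binning strategy {strategy!r}")

    # side='right': a value equal to a cutpoint joins the group whose
    # lower (inclusive) bound it is.
    idx = np.searchsorted(cuts, x, side="right") + 1
    n_groups = len(cuts) + 1
    lo_edges = np.concatenate(([x.min()], cuts))
    hi_edges = np.concatenate((cuts, [x.max()]))
    boundaries = list(zip(lo_edges.tolist(), hi_edges.tolist()))
    fractions = np.bincount(idx, minlength=n_groups + 1)[1:] / x.size
    return BinningResult(group_index=idx, boundaries=boundaries, fractions=fractions)
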