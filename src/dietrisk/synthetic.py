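"""Synthetic residue surveys and FFQ populations.

The raw data behind the Armenian chlorpyrifos assessment — individual
FFQ answers and per-sample chromatograms — are not public; only the
summary marginals in :mod:`dietrisk.datasets` are.  This module
generates populations with exactly those marginals so the full pipeline
is exercisable and testable:

* residue surveys with a *fixed* number of detections (so small-survey
  detection fractions match the published ones exactly, rather than
  binomially on average) and detected values either given explicitly or
  drawn and rescaled to a target mean;
* FFQ populations with fixed-count consumer and frequency-category
  assignment and portion sizes drawn from a right-skewed bounded
  (beta-general) distribution, optionally rescaled so the sample mean
  portion hits a target exactly.

:func:`paper_like_scenario` bundles the calibrated parameters: the
portion and frequency marginals are chosen so the population mean
chronic and acute intakes equal the consumption levels implied by the
published mean EDIs (EDI inverted at the detected mean residue level
and a 71.5 kg body weight).  The real Yerevan portion-size and
frequency distributions are unpublished; the generator's shapes are
synthetic stand-ins constrained only by those means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .consumption import (
    DEFAULT_FREQUENCY_MAP,
    ConsumptionRecord,
    derive_all_intakes,
)
from .datasets import armenia_cpf_survey, implied_mean_consumption
from .distributions import DistributionSpec, sample as _draw
from .residues import ResidueSample

_EDUCATION = ("secondary", "vocational", "higher")
_EMPLOYMENT = ("employed", "self-employed", "unemployed", "retired", "student")
_INCOME = ("low", "middle", "high")


@dataclass(frozen=True)
class ResidueParams:
    """Residue-survey generator settings for one commodity."""

    n_samples: int
    n_detected: int
    value_range: tuple[float, float] = (0.002, 0.005)
    detected_values: tuple[float, ...] | None = None
    target_detected_mean: float | None = None
    lod: float = 0.0003
    loq: float = 0.001

    def __post_init__(self) -> None:
        if not 0 <= self.n_detected <= self.n_samples:
            raise ValueError("need 0 <= n_detected <= n_samples")
        if self.detected_values is not None and len(self.detected_values) != self.n_detected:
            raise ValueError("detected_values length must equal n_detected")


@dataclass(frozen=True)
class CommodityParams:
    """FFQ and residue settings for one commodity."""

    consumer_fraction: float
    portion_dist: DistributionSpec  # grams per eating occasion
    frequency_probs: Mapping[str, float]  # over consuming categories
    residue: ResidueParams
    portion_mean_g: float | None = None  # rescale sample mean to this

    def __post_init__(self) -> None:
        if not 0 <= self.consumer_fraction <= 1:
            raise ValueError("consumer_fraction must be in [0, 1]")
        total = sum(self.frequency_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"frequency probabilities sum to {total}, not 1")
        for cat in self.frequency_probs:
            if DEFAULT_FREQUENCY_MAP.get(cat, 1.0) == 0.0:
                raise ValueError("frequency_probs cover consuming categories only")


@dataclass(frozen=True)
class ScenarioParams:
    """Full synthetic-scenario parameter bundle."""

    n_respondents: int
    commodities: Mapping[str, CommodityParams]
    bw: float = 71.5
    analyte: str = "chlorpyrifos"
    n_male: int | None = None  # demographic quota; None => 50/50
    seed: int = 0


def _fixed_counts(probs: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder allocation of n units to the given proportions."""
    p = np.asarray(probs, dtype=float)
    raw = p * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def generate_residue_survey(
    params: ScenarioParams, commodity: str, seed: int | None = None
) -> list[ResidueSample]:
    """Generate one commodity's residue survey.

    Exactly ``n_detected`` samples are detected.  Detected values come
    from ``detected_values`` verbatim when given, otherwise uniformly
    from ``value_range``, multiplicatively rescaled to
    ``target_detected_mean`` when set.
    """
    cp = params.commodities[commodity]
    rp = cp.residue
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if rp.detected_values is not None:
        values = np.asarray(rp.detected_values, dtype=float)
    else:
        values = rng.uniform(*rp.value_range, size=rp.n_detected)
        if rp.target_detected_mean is not None and values.size:
            values = values * (rp.target_detected_mean / values.mean())
    samples = [
        ResidueSample(commodity, params.analyte, True, float(v), rp.lod, rp.loq)
        for v in values
    ] + [
        ResidueSample(commodity, params.analyte, False, None, rp.lod, rp.loq)
        for _ in range(rp.n_samples - rp.n_detected)
    ]
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]


def _demographics(n: int, n_male: int, rng: np.random.Generator) -> list[dict]:
    gender = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(gender)
    ages = rng.integers(18, 76, size=n)
    return [
        {
            "gender": str(gender[i]),
            "age": str(int(ages[i])),
            "education": str(rng.choice(_EDUCATION)),
            "employment": str(rng.choice(_EMPLOYMENT)),
            "income": str(rng.choice(_INCOME)),
        }
        for i in range(n)
    ]


def generate_ffq_population(
    params: ScenarioParams, seed: int | None = None
) -> list[ConsumptionRecord]:
    """Generate the FFQ table: one record per respondent x commodity.

    Consumer counts and frequency-category counts are fixed (largest
    remainder), so configured fractions are met exactly up to integer
    rounding.  Portions are drawn per consumer from the commodity's
    portion distribution; when ``portion_mean_g`` is set, drawn portions
    are rescaled so their sample mean equals it exactly.  Intakes are
    derived on the way out.
    """
    master = np.random.SeedSequence(params.seed if seed is None else seed)
    streams = master.spawn(1 + len(params.commodities))
    rng_demo = np.random.default_rng(streams[0])

    n = params.n_respondents
    n_male = params.n_male if params.n_male is not None else n // 2
    demos = _demographics(n, n_male, rng_demo)
    ids = [f"R{i + 1:04d}" for i in range(n)]

    records: list[ConsumptionRecord] = []
    for k, commodity in enumerate(sorted(params.commodities)):
        cp = params.commodities[commodity]
        rng = np.random.default_rng(streams[1 + k])
        n_cons = round(cp.consumer_fraction * n)
        consumer_idx = rng.choice(n, size=n_cons, replace=False)
        is_consumer = np.zeros(n, dtype=bool)
        is_consumer[consumer_idx] = True

        cats = list(cp.frequency_probs)
        counts = _fixed_counts([cp.frequency_probs[c] for c in cats], n_cons)
        cat_assign = np.repeat(np.arange(len(cats)), counts)
        rng.shuffle(cat_assign)

        portions = _draw(cp.portion_dist, n_cons, rng)
        if cp.portion_mean_g is not None and n_cons:
            portions = portions * (cp.portion_mean_g / portions.mean())

        j = 0
        for i in range(n):
            if is_consumer[i]:
                rec = ConsumptionRecord(
                    respondent_id=ids[i],
                    commodity=commodity,
                    frequency_category=cats[int(cat_assign[j])],
                    portion_g=float(portions[j]),
                    demographics=demos[i],
                )
                j += 1
            else:
                rec = ConsumptionRecord(
                    respondent_id=ids[i],
                    commodity=commodity,
                    frequency_category="no consumption",
                    portion_g=None,
                    demographics=demos[i],
                )
            records.append(rec)

    derived, excluded = derive_all_intakes(records)
    assert not excluded  # generator never emits consuming records without portions
    return derived


def calibrate_frequency_probs(
    target_events_per_day: float,
    fixed: Mapping[str, float] | None = None,
    anchor_high: str = "once a day",
    anchor_low: str = "once a week",
) -> dict[str, float]:
    """Category probabilities whose mean events/day hits a target.

    Holds a small fixed mass on mid-frequency categories and solves the
    remaining split between a high- and a low-rate anchor category so
    the expected events/day equals ``target_events_per_day`` exactly.
    """
    if fixed is None:
        fixed = {
            "2-4 times per week": 0.10,
            "2-3 times per month": 0.03,
            "once a month": 0.02,
        }
    r_hi = DEFAULT_FREQUENCY_MAP[anchor_high]
    r_lo = DEFAULT_FREQUENCY_MAP[anchor_low]
    m_fixed = sum(DEFAULT_FREQUENCY_MAP[c] * p for c, p in fixed.items())
    q = 1.0 - sum(fixed.values())
    q_lo = (q * r_hi - (target_events_per_day - m_fixed)) / (r_hi - r_lo)
    q_hi = q - q_lo
    if not (0 <= q_lo <= q and 0 <= q_hi <= q):
        raise ValueError(
            f"target rate {target_events_per_day} not reachable with these anchors"
        )
    probs = dict(fixed)
    probs[anchor_high] = q_hi
    probs[anchor_low] = q_lo
    return probs


def paper_like_scenario(seed: int = 0) -> ScenarioParams:
    """The calibrated scenario reproducing the published marginals.

    Residue surveys use the published detection counts and detected
    concentrations.  Portion and frequency parameters are set so the
    population mean acute portion equals the consumption implied by the
    published mean acute EDI, and the mean events/day then brings the
    mean chronic intake to the level implied by the mean chronic EDI.
    Portion shapes are beta-general (right-skewed, bounded), a stand-in
    for the unpublished survey marginals.
    """
    s = armenia_cpf_survey()
    portion_shapes = {
        "tomato": DistributionSpec("beta_general", (2.0, 4.0, 50.0, 1200.0)),
        "cucumber": DistributionSpec("beta_general", (2.0, 4.0, 30.0, 700.0)),
    }
    commodities = {}
    for com in s.commodities:
        portion_mean = 1000.0 * implied_mean_consumption(s, com, "acute")
        chronic_mean = implied_mean_consumption(s, com, "chronic")
        target_rate = 1000.0 * chronic_mean / portion_mean
        res = s.residues[com]
        commodities[com] = CommodityParams(
            consumer_fraction=s.consumers[com] / s.n_respondents,
            portion_dist=portion_shapes[com],
            portion_mean_g=portion_mean,
            frequency_probs=calibrate_frequency_probs(target_rate),
            residue=ResidueParams(
                n_samples=res.n_samples,
                n_detected=res.n_detected,
                detected_values=res.detected_values,
                lod=res.lod,
                loq=res.loq,
            ),
        )
    return ScenarioParams(
        n_respondents=s.n_respondents,
        commodities=commodities,
        bw=s.refs.bw,
        n_male=s.n_male,
        seed=seed,
    )
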