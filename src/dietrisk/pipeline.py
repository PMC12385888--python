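"""End-to-end assessment pipeline.

``assess`` turns a residue survey plus an FFQ table into the
deterministic report surface: residue summary, chronic/acute EDI by
consumer group, MOE/HQ tables and the cumulative rows.  ``simulate``
builds Monte Carlo input distributions from the same data and
propagates them through the risk metrics, with a Spearman sensitivity
ranking per output.

Conventions
-----------
* Mean MOE/HQ rows transform the corresponding mean EDI (MOE of the
  mean, not mean of the MOEs), and ranges transform the EDI range
  endpoints; the cumulative EDI range is the sum of the per-commodity
  range endpoints.
* Consumer groups are formed on chronic intake (consumers only) and the
  same assignment is reused for the acute table, so a respondent sits
  in one group across horizons.
* Monte Carlo consumption inputs are beta-general fits to the
  individual intakes; residue inputs are a mean-preserving triangular
  over the detected concentrations (a point mass when all detections
  are equal) — small residue surveys cannot support a likelihood fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import risk as rk
from .consumption import BinningResult, ConsumptionRecord, bin_consumers, trim_outliers
from .distributions import DistributionSpec, fit_distribution
from .montecarlo import SimulationResult, run_monte_carlo, sensitivity
from .residues import CensoringRule, ResidueSample, ResidueSummary, summarize_residues
from .risk import ReferenceValues


@dataclass(frozen=True)
class MonteCarloSettings:
    n_iterations: int = 10_000
    seed: int = 0
    metrics: tuple[str, ...] = ("moe", "cum_moe", "hq", "hi")


@dataclass(frozen=True)
class RunConfig:
    """Assessment configuration (censoring, binning, references, MC)."""

    censoring_rule: CensoringRule | str = CensoringRule.DETECTED_ONLY
    refs: ReferenceValues = field(default_factory=ReferenceValues)
    arfd_basis: str = "low"
    binning_strategy: str = "equal_count"
    n_groups: int = 5
    cutpoints: Mapping[str, Sequence[float]] | None = None
    trim_upper: float = 0.0  # upper-tail trim fraction on chronic intakes
    mc: MonteCarloSettings = field(default_factory=MonteCarloSettings)


@dataclass(frozen=True)
class AssessmentResult:
    """Deterministic report surface of one assessment run."""

    residue_table: pd.DataFrame
    chronic_edi_table: pd.DataFrame
    acute_edi_table: pd.DataFrame
    moe_table: pd.DataFrame
    hq_table: pd.DataFrame
    residue_summaries: Mapping[str, ResidueSummary]
    groupings: Mapping[str, BinningResult]
    intakes: Mapping[str, pd.DataFrame]
    config: RunConfig

    @property
    def commodities(self) -> tuple[str, ...]:
        return tuple(sorted(self.residue_summaries))

    def cumulative_chronic_edi(self) -> float:
        t = self.chronic_edi_table
        return float(t.loc[(t.commodity == "combined") & (t.scope == "all_consumers"), "edi_mean"].iloc[0])

    def cumulative_acute_edi(self) -> float:
        t = self.acute_edi_table
        return float(t.loc[(t.commodity == "combined") & (t.scope == "all_consumers"), "edi_mean"].iloc[0])

    def hazard_index(self) -> float:
        t = self.hq_table
        return float(t.loc[(t.commodity == "combined") & (t.scope == "all_consumers"), "hq_mean"].iloc[0])

    def cumulative_moe(self) -> float:
        t = self.moe_table
        return float(t.loc[(t.commodity == "combined") & (t.scope == "all_consumers"), "moe_mean"].iloc[0])


def _consumer_intakes(
    records: Sequence[ConsumptionRecord], commodity: str, trim_upper: float
) -> pd.DataFrame:
    rows = [
        {
            "respondent_id": r.respondent_id,
            "chronic": r.chronic_intake_kg_day,
            "acute": r.acute_intake_kg,
        }
        for r in records
        if r.commodity == commodity and r.is_consumer
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if trim_upper > 0:
        kept, _ = trim_outliers(df["chronic"].to_numpy(), trim_upper)
        cutoff = kept.max()
        df = df[df["chronic"] <= cutoff].reset_index(drop=True)
    return df


def _edi_rows(
    commodity: str,
    intakes: np.ndarray,
    grouping: BinningResult,
    c_content: float,
    bw: float,
) -> list[dict]:
    edis = c_content * intakes / bw
    rows = [{
        "commodity": commodity,
        "scope": "all_consumers",
        "fraction_of_consumers": 1.0,
        "n": int(edis.size),
        "edi_mean": float(edis.mean()),
        "edi_min": float(edis.min()),
        "edi_max": float(edis.max()),
    }]
    for g in range(1, grouping.k + 1):
        mask = grouping.group_index == g
        if not mask.any():
            continue
        rows.append({
            "commodity": commodity,
            "scope": f"group {g}",
            "fraction_of_consumers": float(grouping.fractions[g - 1]),
            "n": int(mask.sum()),
            "edi_mean": float(edis[mask].mean()),
            "edi_min": float(edis[mask].min()),
            "edi_max": float(edis[mask].max()),
        })
    return rows


def _combined_row(rows_by_commodity: list[pd.DataFrame]) -> dict:
    means = mins = maxs = 0.0
    for df in rows_by_commodity:
        head = df[df.scope == "all_consumers"].iloc[0]
        means += head.edi_mean
        mins += head.edi_min
        maxs += head.edi_max
    return {
        "commodity": "combined",
        "scope": "all_consumers",
        "fraction_of_consumers": 1.0,
        "n": int(sum(df[df.scope == "all_consumers"].iloc[0]["n"] for df in rows_by_commodity)),
        "edi_mean": means,
        "edi_min": mins,
        "edi_max": maxs,
    }


def _risk_table(edi_table: pd.DataFrame, metric: str, refs: ReferenceValues, arfd_basis: str) -> pd.DataFrame:
    rows = []
    for _, r in edi_table.iterrows():
        if metric == "moe":
            mean = rk.moe(r.edi_mean, refs.hbgv_loael)
            # larger EDI => smaller MOE: range endpoints swap
            lo = rk.moe(r.edi_max, refs.hbgv_loael)
            hi = rk.moe(r.edi_min, refs.hbgv_loael)
            cls = rk.classify_chronic(mean, refs)
            rows.append({
                "commodity": r.commodity, "scope": r.scope,
                "moe_mean": mean, "moe_min": lo, "moe_max": hi,
                "classification": cls.value,
            })
        else:
            arfd = refs.arfd(arfd_basis)
            mean = rk.hq(r.edi_mean, arfd)
            cls = rk.classify_acute(mean, refs)
            rows.append({
                "commodity": r.commodity, "scope": r.scope,
                "hq_mean": mean,
                "hq_min": rk.hq(r.edi_min, arfd),
                "hq_max": rk.hq(r.edi_max, arfd),
                "classification": cls.value,
            })
    return pd.DataFrame(rows)


def assess(
    residue_samples: Sequence[ResidueSample],
    consumption_records: Sequence[ConsumptionRecord],
    config: RunConfig | None = None,
) -> AssessmentResult:
    """Deterministic assessment of a residue survey plus FFQ table."""
    config = config or RunConfig()
    refs = config.refs

    by_commodity: dict[str, list[ResidueSample]] = {}
    for s in residue_samples:
        by_commodity.setdefault(s.commodity, []).append(s)
    summaries = {
        com: summarize_residues(samples, config.censoring_rule)
        for com, samples in by_commodity.items()
    }
    residue_table = pd.DataFrame([
        {
            "commodity": s.commodity,
            "n_samples": s.n_samples,
            "nd_fraction": 1.0 - s.detection_fraction,
            "mean": s.mean,
            "sd": s.sd,
            "min": s.min,
            "max": s.max,
            "censoring_rule": s.censoring_rule.value,
        }
        for s in summaries.values()
    ]).sort_values("commodity").reset_index(drop=True)

    groupings: dict[str, BinningResult] = {}
    intakes: dict[str, pd.DataFrame] = {}
    chronic_frames, acute_frames = [], []
    for com in sorted(summaries):
        df = _consumer_intakes(consumption_records, com, config.trim_upper)
        if df.empty:
            continue
        intakes[com] = df
        cuts = config.cutpoints.get(com) if config.cutpoints else None
        strategy = "explicit_cutpoints" if cuts is not None else config.binning_strategy
        grouping = bin_consumers(
            df["chronic"].to_numpy(), strategy, k=config.n_groups, cutpoints=cuts
        )
        groupings[com] = grouping
        c = summaries[com].mean
        chronic_frames.append(pd.DataFrame(
            _edi_rows(com, df["chronic"].to_numpy(), grouping, c, refs.bw)
        ))
        acute_frames.append(pd.DataFrame(
            _edi_rows(com, df["acute"].to_numpy(), grouping, c, refs.bw)
        ))

    if not chronic_frames:
        empty = pd.DataFrame(columns=[
            "commodity", "scope", "fraction_of_consumers", "n",
            "edi_mean", "edi_min", "edi_max",
        ])
        return AssessmentResult(
            residue_table, empty, empty.copy(),
            pd.DataFrame(), pd.DataFrame(), summaries, {}, {}, config,
        )

    chronic_edi = pd.concat(
        chronic_frames + [pd.DataFrame([_combined_row(chronic_frames)])],
        ignore_index=True,
    )
    acute_edi = pd.concat(
        acute_frames + [pd.DataFrame([_combined_row(acute_frames)])],
        ignore_index=True,
    )
    moe_table = _risk_table(chronic_edi, "moe", refs, config.arfd_basis)
    hq_table = _risk_table(acute_edi, "hq", refs, config.arfd_basis)
    return AssessmentResult(
        residue_table, chronic_edi, acute_edi, moe_table, hq_table,
        summaries, groupings, intakes, config,
    )


def residue_input_spec(summary: ResidueSummary, samples: Sequence[ResidueSample]) -> DistributionSpec:
    """Monte Carlo residue input from a small detected-value set.

    All detections equal => point mass.  Otherwise a mean-preserving
    triangular over [min, max]: the mode is solved from
    mean = (a + m + b)/3 and clipped into the support.
    """
    detected = sorted(float(s.value) for s in samples if s.detected)
    if not detected:
        raise ValueError("no detected values to build a residue input from")
    a, b = detected[0], detected[-1]
    if a == b:
        return DistributionSpec("point", (a,))
    mean = sum(detected) / len(detected)
    m = min(max(3.0 * mean - a - b, a), b)
    return DistributionSpec("triangular", (a, m, b))


def build_mc_inputs(
    result: AssessmentResult,
    residue_samples: Sequence[ResidueSample],
    horizon: str,
) -> tuple[dict[str, DistributionSpec], dict[str, DistributionSpec]]:
    """Input distributions for the Monte Carlo from an assessed dataset."""
    col = "chronic" if horizon == "chronic" else "acute"
    consumption = {
        com: fit_distribution(df[col].to_numpy(), "beta_general")
        for com, df in result.intakes.items()
    }
    by_com: dict[str, list[ResidueSample]] = {}
    for s in residue_samples:
        by_com.setdefault(s.commodity, []).append(s)
    residue = {
        com: residue_input_spec(result.residue_summaries[com], by_com[com])
        for com in consumption
    }
    return consumption, residue


@dataclass(frozen=True)
class SimulationReport:
    """Monte Carlo results plus sensitivity rankings, per metric."""

    results: Mapping[str, SimulationResult]
    sensitivities: Mapping[str, list[tuple[str, float]]]


def simulate(
    result: AssessmentResult,
    residue_samples: Sequence[ResidueSample],
    config: RunConfig | None = None,
) -> SimulationReport:
    """Probabilistic assessment on the same data as :func:`assess`.

    Single-commodity metrics (moe, hq) run once per commodity under the
    key ``"<metric>:<commodity>"``; cumulative metrics use all
    commodities under their own name.
    """
    config = config or result.config
    refs = config.refs
    results: dict[str, SimulationResult] = {}
    sens: dict[str, list[tuple[str, float]]] = {}

    for metric in config.mc.metrics:
        horizon = "chronic" if metric in ("moe", "cum_moe") else "acute"
        cons, res = build_mc_inputs(result, residue_samples, horizon)
        if metric in ("moe", "hq"):
            for com in sorted(cons):
                sim = run_monte_carlo(
                    {com: cons[com]}, {com: res[com]}, refs, metric,
                    n_iterations=config.mc.n_iterations,
                    seed=config.mc.seed,
                    arfd_basis=config.arfd_basis,
                )
                key = f"{metric}:{com}"
                results[key] = sim
                sens[key] = sensitivity(sim.input_draws, sim.draws)
        else:
            sim = run_monte_carlo(
                cons, res, refs, metric,
                n_iterations=config.mc.n_iterations,
                seed=config.mc.seed,
                arfd_basis=config.arfd_basis,
            )
            results[metric] = sim
            sens[metric] = sensitivity(sim.input_draws, sim.draws)
    return SimulationReport(results=results, sensitivities=sens)
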