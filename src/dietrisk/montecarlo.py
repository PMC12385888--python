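"""Monte Carlo propagation of consumption and residue uncertainty.

Each iteration draws a consumption value (kg/day or kg/occasion) and a
residue concentration (mg/kg) per commodity, forms the EDI, and applies
the requested risk metric:

* ``moe``      — chronic margin of exposure, one commodity;
* ``cum_moe``  — cumulative chronic MOE: EDIs summed within-iteration
  before dividing HBGV;
* ``hq``       — acute hazard quotient, one commodity;
* ``hi``       — hazard index: per-commodity HQs summed within-iteration.

Consumption and residue draws are independent by default (no empirical
correlation structure is assumed); a rank-correlation (Iman-Conover)
hook is available for scenario analysis.  Inputs may be parametric
(:class:`~dietrisk.distributions.DistributionSpec`) or empirical
vectors, which are bootstrap-resampled.

Randomness derives from a single master seed through
``numpy.random.SeedSequence`` spawning, one substream per input stream
in a fixed (sorted-commodity) order, so results are bit-for-bit
reproducible for a given configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .distributions import DistributionSpec, half_sample_mode, sample
from .risk import ReferenceValues

METRICS = ("moe", "cum_moe", "hq", "hi")
_CHRONIC_METRICS = {"moe", "cum_moe"}
_ACUTE_METRICS = {"hq", "hi"}


@dataclass(frozen=True)
class SimulationSummary:
    mean: float
    median: float
    mode: float
    mean_ci90: tuple[float, float]
    p50: float
    p75: float
    p90: float
    p95: float
    min: float
    max: float
    sd: float

    def as_dict(self) -> dict:
        d = {
            "mean": self.mean, "median": self.median, "mode": self.mode,
            "mean_ci90_low": self.mean_ci90[0], "mean_ci90_high": self.mean_ci90[1],
            "p50": self.p50, "p75": self.p75, "p90": self.p90, "p95": self.p95,
            "min": self.min, "max": self.max, "sd": self.sd,
        }
        return d


@dataclass(frozen=True)
class SimulationResult:
    """Draws and summary statistics of one simulated output metric."""

    metric: str
    horizon: str
    n_iterations: int
    seed: int
    draws: np.ndarray
    input_draws: Mapping[str, np.ndarray]
    summary: SimulationSummary
    edi_draws: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def summarize_draws(
    draws: Sequence[float] | np.ndarray, ci_level: float = 0.90
) -> SimulationSummary:
    """Summary statistics of simulation output draws.

    Mean CI by normal approximation (mean +/- z * sd / sqrt(n)); mode by
    the half-sample mode estimator; percentiles by linear interpolation
    (type 7); sd with the n-1 denominator.
    """
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("no draws to summarize")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    z = float(stats.norm.ppf(0.5 + ci_level / 2))
    half = z * sd / np.sqrt(x.size)
    p50, p75, p90, p95 = (float(np.quantile(x, q)) for q in (0.50, 0.75, 0.90, 0.95))
    return SimulationSummary(
        mean=mean,
        median=float(np.median(x)),
        mode=half_sample_mode(x),
        mean_ci90=(mean - half, mean + half),
        p50=p50, p75=p75, p90=p90, p95=p95,
        min=float(x.min()), max=float(x.max()), sd=sd,
    )


InputSource = DistributionSpec | Sequence[float] | np.ndarray


def _draw(source: InputSource, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(source, DistributionSpec):
        return sample(source, n, rng)
    x = np.asarray(source, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("empirical input must be a non-empty 1-D vector")
    return rng.choice(x, size=n, replace=True)  # bootstrap mode


def iman_conover(
    columns: np.ndarray, target_corr: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Reorder sample columns to approximate a target rank correlation.

    Standard Iman-Conover: build van der Waerden score columns with the
    target correlation, then rank-match each input column to the
    corresponding score column.  Marginals are preserved exactly.
    """
    n, k = columns.shape
    c = np.asarray(target_corr, dtype=float)
    if c.shape != (k, k):
        raise ValueError(f"correlation matrix must be {k}x{k}")
    scores = stats.norm.ppf(np.arange(1, n + 1) / (n + 1))
    m = np.column_stack([rng.permutation(scores) for _ in range(k)])
    e = np.corrcoef(m, rowvar=False)
    m = m @ np.linalg.inv(np.linalg.cholesky(e).T) @ np.linalg.cholesky(c).T
    out = np.empty_like(columns)
    for j in range(k):
        order = np.argsort(np.argsort(m[:, j]))
        out[:, j] = np.sort(columns[:, j])[order]
    return out


def run_monte_carlo(
    consumption_specs: Mapping[str, InputSource],
    residue_specs: Mapping[str, InputSource],
    refs: ReferenceValues,
    metric: str,
    horizon: str | None = None,
    n_iterations: int = 10_000,
    seed: int = 0,
    arfd_basis: str = "low",
    rank_correlation: np.ndarray | None = None,
) -> SimulationResult:
    """Propagate input distributions through EDI to a risk metric.

    ``consumption_specs`` and ``residue_specs`` map commodity labels to
    input sources.  Single-commodity metrics (moe, hq) require exactly
    one commodity; cumulative metrics (cum_moe, hi) require matching
    commodity sets in both mappings.  The horizon defaults to the one
    compatible with the metric (chronic for MOE, acute for HQ/HI).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    implied = "chronic" if metric in _CHRONIC_METRICS else "acute"
    horizon = horizon or implied
    if horizon != implied:
        raise ValueError(f"metric {metric!r} is a {implied} metric, not {horizon}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be positive")

    commodities = sorted(consumption_specs)
    if sorted(residue_specs) != commodities:
        raise ValueError(
            "consumption and residue commodity sets differ: "
            f"{commodities} vs {sorted(residue_specs)}"
        )
    if metric in ("moe", "hq") and len(commodities) != 1:
        raise ValueError(f"metric {metric!r} needs exactly one commodity")

    streams = np.random.SeedSequence(seed).spawn(2 * len(commodities) + 1)
    input_draws: dict[str, np.ndarray] = {}
    for i, com in enumerate(commodities):
        rng_c = np.random.default_rng(streams[2 * i])
        rng_r = np.random.default_rng(streams[2 * i + 1])
        input_draws[f"{com} consumption"] = _draw(consumption_specs[com], n_iterations, rng_c)
        input_draws[f"{com} residue"] = _draw(residue_specs[com], n_iterations, rng_r)

    if rank_correlation is not None:
        labels = list(input_draws)
        mat = np.column_stack([input_draws[lb] for lb in labels])
        rng_ic = np.random.default_rng(streams[-1])
        mat = iman_conover(mat, rank_correlation, rng_ic)
        input_draws = {lb: mat[:, j] for j, lb in enumerate(labels)}

    edi_total = np.zeros(n_iterations)
    hq_total = np.zeros(n_iterations)
    arfd = refs.arfd(arfd_basis)
    for com in commodities:
        edi_com = (
            input_draws[f"{com} residue"] * input_draws[f"{com} consumption"] / refs.bw
        )
        edi_total += edi_com
        hq_total += edi_com / arfd

    if metric in ("moe", "cum_moe"):
        with np.errstate(divide="ignore"):
            draws = refs.hbgv_loael / edi_total
    else:
        draws = hq_total

    return SimulationResult(
        metric=metric,
        horizon=horizon,
        n_iterations=n_iterations,
        seed=seed,
        draws=draws,
        input_draws=input_draws,
        summary=summarize_draws(draws),
        edi_draws=edi_total,
    )


def simulate_from_metric_fit(
    metric_values: Sequence[float] | np.ndarray,
    family: str | Sequence[str],
    n_iterations: int = 10_000,
    seed: int = 0,
    criterion: str = "ks",
) -> tuple[DistributionSpec, SimulationResult]:
    """Fit-to-metric simulation mode.

    Fits a distribution to per-respondent metric values (the way
    spreadsheet risk tools fit their output panels) and simulates from
    the fitted spec, rather than propagating the raw inputs.
    """
    from .distributions import fit_distribution, select_best_fit

    if isinstance(family, str):
        spec = fit_distribution(metric_values, family)
    else:
        spec = select_best_fit(metric_values, family, criterion=criterion)
    draws = sample(spec, n_iterations, np.random.default_rng(np.random.SeedSequence(seed)))
    result = SimulationResult(
        metric="fitted",
        horizon="n/a",
        n_iterations=n_iterations,
        seed=seed,
        draws=draws,
        input_draws={},
        summary=summarize_draws(draws),
        edi_draws=np.array([]),
    )
    return spec, result


def sensitivity(
    input_draws: Mapping[str, Sequence[float] | np.ndarray],
    output_draws: Sequence[float] | np.ndarray,
) -> list[tuple[str, float]]:
    """Rank inputs by |Spearman rank correlation| with the output.

    Returns (label, correlation) pairs sorted by descending absolute
    correlation — the convention of tornado-style sensitivity panels.
    Constant inputs get correlation 0.
    """
    y = np.asarray(output_draws, dtype=float)
    out: list[tuple[str, float]] = []
    for label, x in input_draws.items():
        xv = np.asarray(x, dtype=float)
        if xv.shape != y.shape:
            raise ValueError(f"input {label!r} length differs from output")
        if np.ptp(xv) == 0 or np.ptp(y) == 0:
            rho = 0.0
        else:
            rho = float(stats.spearmanr(xv, y).statistic)
        out.append((label, rho))
    out.sort(key=lambda t: abs(t[1]), reverse=True)
    return out
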