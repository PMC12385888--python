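"""Bounded input distributions for Monte Carlo propagation.

Four families cover the inputs and fitted outputs of the simulation:

* ``triangular(a, m, b)`` — minimum, mode, maximum;
* ``pert(a, m, b; lam)`` — the Beta-PERT distribution, a smoothed
  triangular: Beta(1 + lam*(m-a)/(b-a), 1 + lam*(b-m)/(b-a)) rescaled
  to [a, b], with shape lam = 4 by default (mean (a + 4m + b)/6);
* ``beta_general(a1, a2, a, b)`` — a Beta(a1, a2) rescaled to an
  arbitrary finite support [a, b];
* ``point(v)`` — a degenerate point mass, the deterministic limit.

Fitting: triangular and PERT by maximum likelihood (bounds initialised
just outside the data range, mode at the half-sample mode); beta_general
by method of moments on min/max-rescaled data to initialise, refined by
full four-parameter maximum likelihood — the sample extrema understate a
Beta support, so moments alone bias the shape parameters low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

FAMILIES = ("triangular", "pert", "beta_general", "point")


@dataclass(frozen=True)
class DistributionSpec:
    """A distribution family plus its parameters.

    params
        triangular/pert: ``(a, m, b)`` with a <= m <= b;
        beta_general: ``(alpha1, alpha2, a, b)``;
        point: ``(value,)``.
    lam
        PERT shape parameter (ignored by other families).
    meta
        Free-form fitting metadata (e.g. goodness-of-fit ranking).
    """

    family: str
    params: tuple[float, ...]
    lam: float = 4.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        p = self.params
        if self.family in ("triangular", "pert"):
            if len(p) != 3:
                raise ValueError(f"{self.family} needs (a, m, b)")
            a, m, b = p
            if not (a <= m <= b) or not np.isfinite([a, m, b]).all():
                raise ValueError(f"need finite a <= m <= b, got {p}")
            if self.family == "pert" and self.lam <= 0:
                raise ValueError("PERT shape lam must be positive")
        elif self.family == "beta_general":
            if len(p) != 4:
                raise ValueError("beta_general needs (alpha1, alpha2, a, b)")
            a1, a2, a, b = p
            if a1 <= 0 or a2 <= 0:
                raise ValueError("shape parameters must be positive")
            if not a < b or not np.isfinite([a, b]).all():
                raise ValueError("need finite support a < b")
        elif len(p) != 1:
            raise ValueError("point needs (value,)")

    # -- scipy frozen distribution backing the spec ---------------------
    def _frozen(self):
        if self.family == "triangular":
            a, m, b = self.params
            if b == a:
                raise ValueError("degenerate triangular; use a point spec")
            return stats.triang(c=(m - a) / (b - a), loc=a, scale=b - a)
        if self.family == "pert":
            a1, a2, a, b = self._pert_betaparams()
            return stats.beta(a1, a2, loc=a, scale=b - a)
        if self.family == "beta_general":
            a1, a2, a, b = self.params
            return stats.beta(a1, a2, loc=a, scale=b - a)
        raise ValueError("point mass has no continuous scipy counterpart")

    def _pert_betaparams(self) -> tuple[float, float, float, float]:
        a, m, b = self.params
        if b == a:
            raise ValueError("degenerate PERT; use a point spec")
        rng_ = b - a
        return 1 + self.lam * (m - a) / rng_, 1 + self.lam * (b - m) / rng_, a, b

    # -- public API ------------------------------------------------------
    def mean(self) -> float:
        if self.family == "point":
            return float(self.params[0])
        if self.family == "triangular":
            a, m, b = self.params
            return (a + m + b) / 3.0
        if self.family == "pert":
            a, m, b = self.params
            return (a + self.lam * m + b) / (self.lam + 2.0)
        a1, a2, a, b = self.params
        return a + (b - a) * a1 / (a1 + a2)

    def cdf(self, x) -> np.ndarray:
        if self.family == "point":
            return (np.asarray(x, dtype=float) >= self.params[0]).astype(float)
        return self._frozen().cdf(x)

    def ppf(self, q) -> np.ndarray:
        if self.family == "point":
            return np.full_like(np.asarray(q, dtype=float), self.params[0])
        return self._frozen().ppf(q)

    def support(self) -> tuple[float, float]:
        if self.family == "point":
            v = self.params[0]
            return (v, v)
        if self.family == "beta_general":
            return (self.params[2], self.params[3])
        return (self.params[0], self.params[2])


def sample(
    spec: DistributionSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n values from *spec*, reproducible given (spec, n, seed)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.family == "point":
        return np.full(n, float(spec.params[0]))
    if spec.family == "triangular":
        a, m, b = spec.params
        if a == b:
            return np.full(n, a)
        return rng.triangular(a, m, b, size=n)
    if spec.family == "pert":
        a1, a2, a, b = spec._pert_betaparams()
        return a + (b - a) * rng.beta(a1, a2, size=n)
    a1, a2, a, b = spec.params
    return a + (b - a) * rng.beta(a1, a2, size=n)


def half_sample_mode(x: Sequence[float] | np.ndarray) -> float:
    """Robust mode of a continuous sample (half-sample mode, HSM).

    Recursively keeps the shortest half of the sorted sample until at
    most three points remain.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    if xs.size == 0:
        raise ValueError("empty sample")
    while xs.size > 3:
        h = (xs.size + 1) // 2
        widths = xs[h - 1:] - xs[: xs.size - h + 1]
        i = int(np.argmin(widths))
        xs = xs[i : i + h]
    if xs.size == 3:
        # pick the closer pair's midpoint
        return float((xs[0] + xs[1]) / 2 if xs[1] - xs[0] <= xs[2] - xs[1] else (xs[1] + xs[2]) / 2)
    return float(xs.mean())


class FitWarning(UserWarning):
    pass


def _fit_triangular(x: np.ndarray) -> DistributionSpec:
    eps = 1e-9 * max(1.0, float(np.ptp(x)))
    lo, hi = x.min() - eps, x.max() + eps
    m0 = np.clip(half_sample_mode(x), lo, hi)
    c0 = (m0 - lo) / (hi - lo)
    c, loc, scale = stats.triang.fit(x, c0, loc=lo, scale=hi - lo)
    a, b = loc, loc + scale
    m = np.clip(loc + c * scale, a, b)
    return DistributionSpec("triangular", (float(a), float(m), float(b)))


def _fit_pert(x: np.ndarray, lam: float) -> DistributionSpec:
    eps = 1e-9 * max(1.0, float(np.ptp(x)))
    lo, hi = float(x.min()), float(x.max())

    def nll(theta: np.ndarray) -> float:
        a, m, b = theta
        if not (a < lo and b > hi and a < m < b):
            return np.inf
        a1 = 1 + lam * (m - a) / (b - a)
        a2 = 1 + lam * (b - m) / (b - a)
        return -stats.beta.logpdf(x, a1, a2, loc=a, scale=b - a).sum()

    span = hi - lo
    x0 = np.array([lo - 0.01 * span - eps, half_sample_mode(x), hi + 0.01 * span + eps])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000})
    a, m, b = res.x
    return DistributionSpec("pert", (float(a), float(m), float(b)), lam=lam,
                            meta={"converged": bool(res.success)})


def _fit_beta_general(x: np.ndarray) -> DistributionSpec:
    eps = 1e-9 * max(1.0, float(np.ptp(x)))
    a0, b0 = x.min() - eps, x.max() + eps
    y = (x - a0) / (b0 - a0)
    mu, v = y.mean(), y.var()
    k = max(mu * (1 - mu) / max(v, 1e-12) - 1, 1e-3)
    a1_0, a2_0 = max(mu * k, 1e-3), max((1 - mu) * k, 1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a1, a2, loc, scale = stats.beta.fit(x, a1_0, a2_0, loc=a0, scale=b0 - a0)
    return DistributionSpec(
        "beta_general", (float(a1), float(a2), float(loc), float(loc + scale))
    )


def fit_distribution(
    data: Sequence[float] | np.ndarray, family: str, lam: float = 4.0
) -> DistributionSpec:
    """Fit one distribution family to data (>= 10 points).

    Degenerate data (all values equal) collapse to a point spec with a
    warning, whatever family was requested.
    """
    x = np.asarray(data, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 data points to fit a distribution")
    if np.ptp(x) == 0:
        warnings.warn("degenerate data (all equal); returning a point spec", FitWarning)
        return DistributionSpec("point", (float(x[0]),))
    if family == "triangular":
        return _fit_triangular(x)
    if family == "pert":
        return _fit_pert(x, lam)
    if family == "beta_general":
        return _fit_beta_general(x)
    if family == "point":
        warnings.warn("point family requested for non-degenerate data", FitWarning)
        return DistributionSpec("point", (float(x.mean()),))
    raise ValueError(f"unsupported family {family!r}")


def ks_statistic(data: np.ndarray, spec: DistributionSpec) -> float:
    """Kolmogorov-Smirnov distance between data and a fitted spec."""
    return float(stats.kstest(data, spec.cdf).statistic)


def aic(data: np.ndarray, spec: DistributionSpec) -> float:
    n_par = {"triangular": 3, "pert": 3, "beta_general": 4, "point": 1}[spec.family]
    if spec.family == "point":
        return np.inf
    ll = float(spec._frozen().logpdf(data).sum())
    return 2 * n_par - 2 * ll


def select_best_fit(
    data: Sequence[float] | np.ndarray,
    candidates: Sequence[str] = ("triangular", "pert", "beta_general"),
    criterion: str = "ks",
    lam: float = 4.0,
) -> DistributionSpec:
    """Fit each candidate family and return the best by the criterion.

    Criterion "ks" (Kolmogorov-Smirnov statistic, default) or "aic".
    Ties keep the first family in the caller's candidate order; the
    full ranking is attached under ``meta["ranking"]``.
    """
    if not candidates:
        raise ValueError("need at least one candidate family")
    if criterion not in ("ks", "aic"):
        raise ValueError("criterion must be 'ks' or 'aic'")
    x = np.asarray(data, dtype=float)
    fits: list[tuple[float, str, DistributionSpec]] = []
    for fam in candidates:
        spec = fit_distribution(x, fam, lam=lam)
        if spec.family == "point":
            score = 0.0 if np.ptp(x) == 0 else np.inf
        else:
            score = ks_statistic(x, spec) if criterion == "ks" else aic(x, spec)
        fits.append((score, fam, spec))
    best_score = min(f[0] for f in fits)
    ranking = [(fam, score) for score, fam, _ in sorted(fits, key=lambda t: t[0])]
    for score, fam, spec in fits:  # candidate order => stable tie-break
        if score == best_score:
            meta = dict(spec.meta)
            meta.update({"criterion": criterion, "ranking": ranking})
            return DistributionSpec(spec.family, spec.params, lam=spec.lam, meta=meta)
    raise AssertionError("unreachable")
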