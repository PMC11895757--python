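"""Independent parameter priors.

The joint prior is a product of one distribution per free scalar
parameter. Default choices for the dinosaur-style analysis:

* speciation and extinction rates: lognormal with real-space median 0.2
  events/lineage/Myr and log-sd 1.2, whose central 95% interval
  (~0.019–2.1) brackets published diversification-rate estimates across
  many clades (0.02–1.54);
* fossil-sampling rate: exponential with mean 0.2/Myr — one sample per
  lineage per 5 Myr on average, favouring sparse sampling without
  excluding larger values;
* coalescent growth rates: normal(0, 1) per Myr, symmetric about no
  change so decline and expansion are a priori equally likely;
* effective species richness N_f: lognormal, median 100, log-sd 1.5;
* origin age: uniform between the (current) root age and 280 Ma — older
  than any plausible dinosaur origin. The lower bound tracks the root,
  so its density is renormalised by the sampler as the root moves.

All of these are configuration, not code: any entry may be replaced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import TimeGrid, ValidationError

__all__ = ["Prior", "PriorSpec", "default_priors", "log_prior", "sample_prior"]

_FAMILIES = ("lognormal", "exponential", "gamma", "normal", "laplace", "uniform")
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Prior:
    """One marginal prior: a distribution family, its hyperparameters,
    and optional hard bounds (density is -inf outside them)."""

    family: str
    params: dict[str, float]
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(
                f"unknown prior family {self.family!r}; choose from {_FAMILIES}"
            )
        object.__setattr__(self, "_dist", self._make_frozen())

    def _make_frozen(self):
        p = self.params
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))
        if self.family == "exponential":
            return stats.expon(scale=p["mean"])
        if self.family == "gamma":
            return stats.gamma(a=p["shape"], scale=p["scale"])
        if self.family == "normal":
            return stats.norm(loc=p["mu"], scale=p["sigma"])
        if self.family == "laplace":
            return stats.laplace(loc=p["mu"], scale=p["scale"])
        low, high = p["low"], p["high"]
        if high < low:
            raise ValidationError(f"uniform prior with high < low: {p}")
        return stats.uniform(loc=low, scale=high - low)

    def _frozen(self):
        return self._dist

    def log_pdf(self, x: float) -> float:
        """Closed-form log density (fast path for the sampler's hot loop;
        agrees with the scipy frozen distribution)."""
        if self.bounds is not None and not (self.bounds[0] <= x <= self.bounds[1]):
            return -math.inf
        p = self.params
        f = self.family
        if f == "lognormal":
            if x <= 0:
                return -math.inf
            z = (math.log(x) - p["mu"]) / p["sigma"]
            return -0.5 * z * z - math.log(x * p["sigma"]) - _LOG_SQRT_2PI
        if f == "exponential":
            if x < 0:
                return -math.inf
            return -x / p["mean"] - math.log(p["mean"])
        if f == "gamma":
            if x <= 0:
                return -math.inf
            k, s = p["shape"], p["scale"]
            return (k - 1) * math.log(x) - x / s - k * math.log(s) - math.lgamma(k)
        if f == "normal":
            z = (x - p["mu"]) / p["sigma"]
            return -0.5 * z * z - math.log(p["sigma"]) - _LOG_SQRT_2PI
        if f == "laplace":
            return -abs(x - p["mu"]) / p["scale"] - math.log(2 * p["scale"])
        low, high = p["low"], p["high"]
        if high == low:  # degenerate point mass
            return 0.0 if x == low else -math.inf
        if not low <= x <= high:
            return -math.inf
        return -math.log(high - low)

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "uniform" and self.params["low"] == self.params["high"]:
            val = self.params["low"]
            return val if size is None else np.full(size, val)
        out = self._frozen().rvs(size=1 if size is None else size, random_state=rng)
        return float(out[0]) if size is None else out

    def mean(self) -> float:
        return float(self._frozen().mean())

    def var(self) -> float:
        return float(self._frozen().var())

    def median(self) -> float:
        return float(self._frozen().median())


class PriorSpec(dict):
    """Mapping of parameter name -> :class:`Prior`; the joint prior is
    the product of the entries."""

    def require(self, name: str) -> Prior:
        if name not in self:
            raise ValidationError(f"no prior specified for parameter {name!r}")
        return self[name]


def default_priors(model: str, grid: TimeGrid) -> PriorSpec:
    """Default prior specification for ``model`` ('bdsky' or
    'coalescent') on the given grid (one rate entry per bin)."""
    spec = PriorSpec()
    n = grid.n_bins
    if model == "bdsky":
        for i in range(n):
            spec[f"lambda_{i}"] = Prior(
                "lognormal", {"mu": math.log(0.2), "sigma": 1.2}, bounds=(0.0, math.inf)
            )
            spec[f"mu_{i}"] = Prior(
                "lognormal", {"mu": math.log(0.2), "sigma": 1.2}, bounds=(0.0, math.inf)
            )
            spec[f"psi_{i}"] = Prior(
                "exponential", {"mean": 0.2}, bounds=(0.0, math.inf)
            )
        # lower bound tracks the current root age during inference
        spec["origin"] = Prior("uniform", {"low": 0.0, "high": 280.0 - grid.reference_age})
    elif model == "coalescent":
        for i in range(n):
            spec[f"growth_{i}"] = Prior("normal", {"mu": 0.0, "sigma": 1.0})
        spec["n_final"] = Prior(
            "lognormal", {"mu": math.log(100.0), "sigma": 1.5}, bounds=(0.0, math.inf)
        )
    else:
        raise ValidationError(f"unknown model {model!r}")
    return spec


def log_prior(params: dict[str, float], spec: PriorSpec) -> float:
    """Sum of independent log prior densities over ``params``."""
    total = 0.0
    for name, value in params.items():
        total += spec.require(name).log_pdf(value)
        if total == -math.inf:
            return -math.inf
    return total


def sample_prior(spec: PriorSpec, seed: int | np.random.Generator) -> dict[str, float]:
    """One reproducible joint draw from the prior."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return {name: prior.sample(rng) for name, prior in spec.items()}
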