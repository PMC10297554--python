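"""Parameter distributions for the synthetic virtual-patient cohort.

Each of the 19 simulator inputs is described by a :class:`ParameterDistribution`
— a truncated normal, a continuous uniform, or an integer uniform on a closed
interval.  Eight of the inputs (BE_a, Hb, Vt, PEEP, P_EI, FiO2, SvO2, RR)
carry the published moment/bound summary of the source ICU dataset; the
remaining eleven simulator-internal parameters use documented stand-in ranges
chosen to be physiologically plausible for ventilated adult ICU patients.

Truncated normals are sampled from the exact truncated density (inverse-CDF
via :func:`scipy.stats.truncnorm`), never by clipping, so the density at the
bounds is not inflated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "ParameterDistribution",
    "sample_truncated_normal",
    "default_distributions",
    "load_distributions",
    "save_distributions",
    "INPUT_PARAMETERS",
]

#: Column order of the 19 simulator inputs (fixed, also the CSV header order).
INPUT_PARAMETERS: tuple[str, ...] = (
    "v_sR", "v_inR", "v_sVR", "v_inVR", "v_nc", "asht", "RQ", "VO2",
    "VD_phys", "CO", "IE_ratio", "Hb", "FiO2", "PEEP", "P_EI", "SvO2",
    "RR", "Vt", "BE_a",
)

_KINDS = ("truncated_normal", "uniform", "integer_uniform")

#: Minimum Gaussian mass allowed on [min, max] before the truncation is
#: considered degenerate (equivalent to a rejection acceptance rate of 1e-3).
_MIN_ACCEPTANCE = 1e-3


class DistributionError(ValueError):
    """Invalid distribution specification."""


@dataclass(frozen=True)
class ParameterDistribution:
    """Marginal distribution of one simulator input parameter.

    Parameters
    ----------
    name
        Parameter identifier (one of :data:`INPUT_PARAMETERS`).
    mean, sd
        Location and scale of the parent normal, in the parameter's units.
        Ignored for the uniform kinds.
    min, max
        Hard truncation bounds; no sampled value falls outside them.
    kind
        ``truncated_normal`` | ``uniform`` | ``integer_uniform``.
    """

    name: str
    mean: float
    sd: float
    min: float
    max: float
    kind: str = "truncated_normal"

    def __post_init__(self) -> None:
        for field in ("mean", "sd", "min", "max"):
            v = getattr(self, field)
            if not math.isfinite(v):
                raise DistributionError(
                    f"{self.name}: non-finite {field!r} ({v!r})")
        if self.kind not in _KINDS:
            raise DistributionError(
                f"{self.name}: unknown kind {self.kind!r}; expected one of {_KINDS}")
        if not self.min < self.max:
            raise DistributionError(
                f"{self.name}: require min < max, got [{self.min}, {self.max}]")
        if self.sd < 0:
            raise DistributionError(f"{self.name}: sd must be >= 0, got {self.sd}")
        if self.kind == "truncated_normal" and not (self.min <= self.mean <= self.max):
            raise DistributionError(
                f"{self.name}: truncated-normal mean {self.mean} outside "
                f"[{self.min}, {self.max}]")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values; deterministic given the generator state."""
        if n < 0:
            raise DistributionError(f"{self.name}: n must be >= 0, got {n}")
        if self.kind == "uniform":
            return rng.uniform(self.min, self.max, size=n)
        if self.kind == "integer_uniform":
            return rng.integers(int(self.min), int(self.max) + 1, size=n).astype(float)
        return sample_truncated_normal(self, n, rng)


@lru_cache(maxsize=256)
def _matched_parent(mean: float, sd: float, lo: float, hi: float
                    ) -> tuple[float, float]:
    """Parent normal (mu, sigma) whose [lo, hi]-truncation has the given
    mean and standard deviation.

    The published summaries describe the (bounded) source data, i.e. the
    truncated law itself; sampling a parent normal at those parameters and
    truncating would bias the moments, so the parent is solved for instead.
    """
    # the truncated-normal sd cannot exceed the uniform limit width/sqrt(12)
    width = hi - lo
    if sd >= width / math.sqrt(12.0):
        raise DistributionError(
            f"target sd {sd} unattainable for a truncated normal on "
            f"[{lo}, {hi}] (uniform limit {width / math.sqrt(12.0):.4g})")

    def residual(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(residual, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success or max(abs(r) for r in residual(sol.x)) > 1e-6 * max(sd, 1.0):
        raise DistributionError(
            f"moment matching failed for truncated normal "
            f"(mean={mean}, sd={sd}, bounds=[{lo}, {hi}])")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def sample_truncated_normal(dist: ParameterDistribution, n: int,
                            rng: np.random.Generator,
                            match_moments: bool = True) -> np.ndarray:
    """Sample ``n`` values from a normal truncated to [min, max].

    Draws from the exact truncated density, so all values lie strictly inside
    the bounds and the boundary density is not inflated.  ``sd == 0``
    degenerates to a point mass at the mean.

    With ``match_moments`` (the default used by cohort generation)
    ``dist.mean`` / ``dist.sd`` are the target moments of the truncated law —
    what a summary table of bounded source data reports — and the parent
    normal is solved for so the sample reproduces them.  With
    ``match_moments=False`` they parameterize the parent normal directly.

    Raises
    ------
    DistributionError
        If the Gaussian mass on [min, max] is below 1e-3 (the truncation is
        so severe that a rejection sampler would almost never accept — a
        degenerate-bounds configuration error), or if no parent normal can
        attain the requested truncated moments.
    """
    if n < 0:
        raise DistributionError(f"{dist.name}: n must be >= 0, got {n}")
    if dist.sd == 0.0:
        return np.full(n, float(dist.mean))
    if match_moments:
        mu, sigma = _matched_parent(dist.mean, dist.sd, dist.min, dist.max)
    else:
        mu, sigma = dist.mean, dist.sd
    a = (dist.min - mu) / sigma
    b = (dist.max - mu) / sigma
    acceptance = stats.norm.cdf(b) - stats.norm.cdf(a)
    if acceptance < _MIN_ACCEPTANCE:
        raise DistributionError(
            f"{dist.name}: truncation to [{dist.min}, {dist.max}] keeps only "
            f"{acceptance:.2e} of the normal mass (acceptance < {_MIN_ACCEPTANCE})")
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma,
                               size=n, random_state=rng)


def default_distributions() -> list[ParameterDistribution]:
    """The shipped cohort specification, in input-column order.

    The eight published parameters carry the source-dataset mean/SD/min/max
    verbatim; the eleven simulator-internal parameters use stand-in adult-ICU
    ranges (all configurable through a YAML spec file).
    """
    tn = "truncated_normal"
    u = "uniform"
    iu = "integer_uniform"
    specs = [
        # simulator-internal stand-ins
        ParameterDistribution("v_sR", 0.0, 0.0, 0.5, 2.0, u),
        ParameterDistribution("v_inR", 0.0, 0.0, 0.5, 2.0, u),
        ParameterDistribution("v_sVR", 0.0, 0.0, 0.5, 2.0, u),
        ParameterDistribution("v_inVR", 0.0, 0.0, 0.5, 2.0, u),
        ParameterDistribution("v_nc", 0.0, 0.0, 0, 30, iu),
        ParameterDistribution("asht", 0.0, 0.0, 0.01, 0.15, u),
        ParameterDistribution("RQ", 0.8, 0.05, 0.7, 1.0, tn),
        ParameterDistribution("VO2", 0.25, 0.05, 0.15, 0.50, tn),
        ParameterDistribution("VD_phys", 0.15, 0.03, 0.08, 0.30, tn),
        ParameterDistribution("CO", 5.0, 1.0, 2.5, 9.0, tn),
        ParameterDistribution("IE_ratio", 0.0, 0.0, 0.33, 1.0, u),
        # published source-dataset summary
        ParameterDistribution("Hb", 9.15, 1.17, 6, 12, tn),
        ParameterDistribution("FiO2", 41.08, 12.39, 20, 100, tn),
        ParameterDistribution("PEEP", 8.64, 3.15, 0, 24, tn),
        ParameterDistribution("P_EI", 21.68, 5.76, 0, 40, tn),
        ParameterDistribution("SvO2", 68.81, 11.03, 30, 100, tn),
        ParameterDistribution("RR", 20.83, 5.73, 10, 40, tn),
        ParameterDistribution("Vt", 463.80, 115.13, 220, 840, tn),
        ParameterDistribution("BE_a", 1.37, 4.42, -15, 15, tn),
    ]
    assert tuple(s.name for s in specs) == INPUT_PARAMETERS
    return specs


def save_distributions(specs: Iterable[ParameterDistribution], path) -> None:
    """Write a distribution spec file (YAML list of records)."""
    records = [asdict(s) for s in specs]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(records, fh, sort_keys=False)


def load_distributions(path) -> list[ParameterDistribution]:
    """Read a distribution spec file written by :func:`save_distributions`."""
    with open(path, encoding="utf-8") as fh:
        records = yaml.safe_load(fh)
    if not isinstance(records, Sequence):
        raise DistributionError(f"{path}: expected a list of parameter records")
    return [ParameterDistribution(**r) for r in records]
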