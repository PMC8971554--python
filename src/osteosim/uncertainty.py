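"""Moment-matched sampling distributions for probabilistic sensitivity analysis.

Families follow standard health-economics practice: beta for
probabilities and utilities, gamma for costs, lognormal for relative
risks.  Hyperparameters are stored as (mean, sd) for beta/gamma and
(mu, sigma) for lognormal; zero spread denotes a point mass.
"""

from __future__ import annotations

import math

import numpy as np

from .params import PsaDistribution


def beta_from_mean_sd(mean: float, sd: float) -> PsaDistribution:
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0,1), got {mean}")
    if sd < 0 or sd * sd >= mean * (1.0 - mean):
        raise ValueError(f"beta sd {sd} too large for mean {mean}")
    return PsaDistribution("beta", {"mean": mean, "sd": sd})


def gamma_from_mean_sd(mean: float, sd: float) -> PsaDistribution:
    if mean <= 0 or sd < 0:
        raise ValueError("gamma requires mean > 0 and sd >= 0")
    return PsaDistribution("gamma", {"mean": mean, "sd": sd})


def lognormal_from_bounds(point: float, low: float, high: float) -> PsaDistribution:
    """Median at the point estimate, sigma from the 95% bound ratio."""
    if not 0 < low <= point <= high:
        raise ValueError("require 0 < low <= point <= high")
    sigma = (math.log(high) - math.log(low)) / (2.0 * 1.959963984540054)
    return PsaDistribution("lognormal", {"mu": math.log(point), "sigma": sigma})


def sample_distribution(dist: PsaDistribution, rng: np.random.Generator) -> float:
    """Draw one value; point masses consume no randomness."""
    p = dist.params
    if dist.family == "beta":
        m, s = p["mean"], p["sd"]
        if s == 0.0:
            return m
        nu = m * (1.0 - m) / (s * s) - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    if dist.family == "gamma":
        m, s = p["mean"], p["sd"]
        if s == 0.0:
            return m
        shape = (m / s) ** 2
        return float(rng.gamma(shape, s * s / m))
    if dist.family == "lognormal":
        mu, sigma = p["mu"], p["sigma"]
        if sigma == 0.0:
            return math.exp(mu)
        return float(rng.lognormal(mu, sigma))
    raise ValueError(f"unknown distribution family {dist.family!r}")


def distribution_mean(dist: PsaDistribution) -> float:
    p = dist.params
    if dist.family in ("beta", "gamma"):
        return p["mean"]
    if dist.family == "lognormal":
        return math.exp(p["mu"] + 0.5 * p["sigma"] ** 2)
    raise ValueError(f"unknown distribution family {dist.family!r}")
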