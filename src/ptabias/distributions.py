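"""Population distributions for PK quantities (clearance, unbound fraction).

Three sampling laws cover everything the simulation pipeline needs: a
lognormal parameterized by its arithmetic mean and coefficient of variation
(the convention in which population PK variability is reported), a uniform
on a positive interval, and a degenerate scalar. Every spec is a frozen
dataclass and serializes to a tagged dict for config files.

Reproducibility follows a named-substream policy: a scenario's master seed
spawns independent child streams (clearance, generating fu, scaling fu) via
``numpy.random.SeedSequence`` spawn keys, so adding or removing one sampling
stage never perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "LognormalSpec",
    "UniformSpec",
    "ScalarSpec",
    "DistributionSpec",
    "lognormal_from_mean_cv",
    "sample",
    "substream_rng",
    "spec_to_dict",
    "spec_from_dict",
    "STREAMS",
]

#: Named substreams of a scenario master seed. The spawn key, not the call
#: order, identifies the stream.
STREAMS = {"clearance": 0, "fu_generate": 1, "fu_scale": 2}


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal law stated by arithmetic mean and CV.

    ``mu`` and ``sigma`` are the log-scale (normal) parameters, derived as
    sigma = sqrt(ln(1 + cv^2)), mu = ln(mean) - sigma^2 / 2 so that the
    arithmetic mean of ``exp(N(mu, sigma^2))`` equals ``mean`` exactly.
    """

    mean: float
    cv: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.mean > 0):
            raise ValueError(f"lognormal mean must be positive, got {self.mean}")
        if self.cv < 0:
            raise ValueError(f"lognormal cv must be non-negative, got {self.cv}")


@dataclass(frozen=True)
class UniformSpec:
    """Uniform law on [lo, hi], 0 < lo < hi."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"uniform bounds must satisfy 0 < lo < hi, got ({self.lo}, {self.hi})"
            )

    @property
    def mean(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class ScalarSpec:
    """Degenerate law: every draw equals ``value``."""

    value: float

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValueError(f"scalar value must be positive, got {self.value}")

    @property
    def mean(self) -> float:
        return self.value


DistributionSpec = Union[LognormalSpec, UniformSpec, ScalarSpec]


def lognormal_from_mean_cv(mean: float, cv: float) -> LognormalSpec:
    """Build a :class:`LognormalSpec` from arithmetic mean and CV.

    Round-trips with the (mu, sigma) parameterization to machine precision:
    ``exp(mu + sigma^2/2) == mean`` and ``sqrt(exp(sigma^2) - 1) == cv``.
    """
    if not (mean > 0):
        raise ValueError(f"mean must be positive, got {mean}")
    if cv < 0:
        raise ValueError(f"cv must be non-negative, got {cv}")
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = math.log(mean) - 0.5 * sigma * sigma
    return LognormalSpec(mean=mean, cv=cv, mu=mu, sigma=sigma)


def substream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named substream of a master seed."""
    if stream not in STREAMS:
        raise KeyError(f"unknown stream {stream!r}; expected one of {sorted(STREAMS)}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(STREAMS[stream],))
    return np.random.default_rng(ss)


def sample(
    spec: DistributionSpec,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` values from ``spec``; deterministic given (spec, n, seed).

    ``seed`` may be an integer (a fresh generator is built from it) or an
    already-positioned :class:`numpy.random.Generator` (used by the scenario
    engine to route draws through named substreams).
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(spec, LognormalSpec):
        return rng.lognormal(mean=spec.mu, sigma=spec.sigma, size=n)
    if isinstance(spec, UniformSpec):
        return rng.uniform(spec.lo, spec.hi, size=n)
    if isinstance(spec, ScalarSpec):
        return np.full(n, spec.value, dtype=float)
    raise TypeError(f"unsupported spec type: {type(spec).__name__}")


def spec_to_dict(spec: DistributionSpec) -> dict:
    """Serialize a spec to a kind-tagged dict (config-file form)."""
    if isinstance(spec, LognormalSpec):
        return {"kind": "lognormal", "mean": spec.mean, "cv": spec.cv}
    if isinstance(spec, UniformSpec):
        return {"kind": "uniform", "lo": spec.lo, "hi": spec.hi}
    if isinstance(spec, ScalarSpec):
        return {"kind": "scalar", "value": spec.value}
    raise TypeError(f"unsupported spec type: {type(spec).__name__}")


def spec_from_dict(d: dict) -> DistributionSpec:
    """Inverse of :func:`spec_to_dict`; raises ``ValueError`` on bad input."""
    try:
        kind = d["kind"]
    except (TypeError, KeyError):
        raise ValueError(f"distribution spec must be a dict with a 'kind' tag, got {d!r}")
    if kind == "lognormal":
        return lognormal_from_mean_cv(float(d["mean"]), float(d["cv"]))
    if kind == "uniform":
        return UniformSpec(float(d["lo"]), float(d["hi"]))
    if kind == "scalar":
        return ScalarSpec(float(d["value"]))
    raise ValueError(f"unknown distribution kind {kind!r}")
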