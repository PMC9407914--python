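"""Seeded synthetic cohorts shaped like a population CVD-screening study.

The generator emulates a cohort of ~4000 adults screened for cardiovascular
risk: a binary outcome (high/low estimated CVD risk, prevalence ~0.444),
a handful of categorical lifestyle covariates with fixed marginal
frequencies, a strong binary risk score, a protective education gradient,
and six "random" candidate markers drawn independently of the outcome from
uniform(0, 100), normal(0, 1), Poisson(4), exponential(rate 1) and
Bernoulli(0.1 / 0.5) distributions.

Outcomes follow a logistic model on the covariate effects; the intercept is
calibrated by monotone root finding so the expected prevalence hits the
configured target. Covariates are sampled independently of each other (only
marginal frequencies are specified), each from its own seed substream so
adding or removing one column never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .core import SchemaError

__all__ = [
    "CategoricalCovariate",
    "RandomMarker",
    "CohortConfig",
    "CalibrationError",
    "default_config",
    "load_config",
    "calibrate_intercept",
    "generate_cohort",
]


class CalibrationError(RuntimeError):
    """Target prevalence unreachable for the configured effects."""


@dataclass(frozen=True)
class CategoricalCovariate:
    """A categorical covariate with marginal frequencies and log-odds effects.

    ``role`` is "base" for covariates available to the base model and
    "marker" for candidate markers added one at a time to extend it.
    ``logodds`` are conditional effects on the outcome's linear predictor
    (reference category 0 by convention).
    """

    name: str
    categories: tuple[str, ...]
    freqs: tuple[float, ...]
    logodds: tuple[float, ...]
    role: str = "base"

    def __post_init__(self) -> None:
        if not (len(self.categories) == len(self.freqs) == len(self.logodds)):
            raise SchemaError(f"covariate {self.name!r}: ragged spec")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise SchemaError(f"covariate {self.name!r}: frequencies must sum to 1")
        if self.role not in ("base", "marker"):
            raise SchemaError(f"covariate {self.name!r}: unknown role {self.role!r}")

    @property
    def reference(self) -> str:
        """Reference category: the one with zero log-odds (first such)."""
        for cat, lo in zip(self.categories, self.logodds):
            if lo == 0.0:
                return cat
        return self.categories[0]


@dataclass(frozen=True)
class RandomMarker:
    """A candidate marker sampled independently of the outcome."""

    name: str
    dist: str
    params: dict

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "uniform":
            return rng.uniform(self.params["low"], self.params["high"], n)
        if self.dist == "normal":
            return rng.normal(self.params.get("mean", 0.0), self.params.get("sd", 1.0), n)
        if self.dist == "poisson":
            return rng.poisson(self.params["lam"], n).astype(float)
        if self.dist == "exponential":
            return rng.exponential(1.0 / self.params["rate"], n)
        if self.dist == "bernoulli":
            return rng.binomial(1, self.params["p"], n).astype(float)
        raise SchemaError(f"unknown marker distribution {self.dist!r}")


@dataclass(frozen=True)
class CohortConfig:
    n: int = 3971
    target_prevalence: float = 1765 / 3971
    covariates: tuple[CategoricalCovariate, ...] = ()
    random_markers: tuple[RandomMarker, ...] = ()

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise SchemaError("n must be positive")
        if not (0.0 < self.target_prevalence < 1.0):
            raise CalibrationError("target prevalence must lie in (0, 1)")

    @property
    def base_covariates(self) -> list[str]:
        return [c.name for c in self.covariates if c.role == "base"]

    @property
    def marker_covariates(self) -> list[str]:
        return [c.name for c in self.covariates if c.role == "marker"]

    def covariate(self, name: str) -> CategoricalCovariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def references(self) -> dict[str, str]:
        """Reference category per covariate, for dummy coding."""
        return {c.name: c.reference for c in self.covariates}

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "target_prevalence": self.target_prevalence,
            "covariates": [
                {
                    "name": c.name,
                    "role": c.role,
                    "categories": list(c.categories),
                    "freqs": list(c.freqs),
                    "logodds": list(c.logodds),
                }
                for c in self.covariates
            ],
            "random_markers": [
                {"name": m.name, "dist": m.dist, "params": m.params}
                for m in self.random_markers
            ],
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return format(zlib.crc32(payload), "08x")

    def model_hash(self) -> str:
        """Hash of the outcome model only (covariate effects + target
        prevalence): random-marker specs and n do not enter, so the
        calibrated intercept is unaffected by adding markers or resizing."""
        d = self.to_dict()
        payload = json.dumps(
            {"target_prevalence": d["target_prevalence"], "covariates": d["covariates"]},
            sort_keys=True,
        ).encode()
        return format(zlib.crc32(payload), "08x")


def _config_from_dict(d: dict) -> CohortConfig:
    covs = tuple(
        CategoricalCovariate(
            name=c["name"],
            categories=tuple(c["categories"]),
            freqs=tuple(float(f) for f in c["freqs"]),
            logodds=tuple(float(v) for v in c["logodds"]),
            role=c.get("role", "base"),
        )
        for c in d.get("covariates", [])
    )
    marks = tuple(
        RandomMarker(name=m["name"], dist=m["dist"], params=dict(m["params"]))
        for m in d.get("random_markers", [])
    )
    return CohortConfig(
        n=int(d.get("n", 3971)),
        target_prevalence=float(d.get("target_prevalence", 1765 / 3971)),
        covariates=covs,
        random_markers=marks,
    )


def load_config(path) -> CohortConfig:
    """Load a cohort configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def default_config(n: int | None = None) -> CohortConfig:
    """The packaged default cohort configuration (versioned YAML)."""
    text = resources.files("reclasskappa.data").joinpath("default_config.yaml").read_text()
    cfg = _config_from_dict(yaml.safe_load(text))
    if n is not None:
        cfg = _config_from_dict({**cfg.to_dict(), "n": n})
    return cfg


def _column_rng(seed: int, name: str) -> np.random.Generator:
    """Independent substream per column: stable in the column name only."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


def _sample_covariates(config: CohortConfig, seed: int, n: int) -> pd.DataFrame:
    cols = {}
    for cov in config.covariates:
        rng = _column_rng(seed, f"covariate:{cov.name}")
        idx = rng.choice(len(cov.categories), size=n, p=cov.freqs)
        cols[cov.name] = pd.Categorical.from_codes(
            idx, categories=list(cov.categories)
        )
    return pd.DataFrame(cols, index=pd.RangeIndex(n))


def _linear_predictor(config: CohortConfig, covariates: pd.DataFrame) -> np.ndarray:
    eta = np.zeros(len(covariates))
    for cov in config.covariates:
        lo = np.asarray(cov.logodds)
        codes = covariates[cov.name].cat.codes.to_numpy()
        eta += lo[codes]
    return eta


_CALIBRATION_CACHE: dict[tuple[str, int, int], float] = {}


def calibrate_intercept(
    config: CohortConfig, n_mc: int = 200_000, tol: float = 1e-4, seed: int | None = None
) -> float:
    """Intercept beta0 such that E[expit(beta0 + eta)] hits the target.

    The expectation is over a Monte-Carlo draw of the covariates (size
    ``n_mc``); mean prevalence is a strictly increasing function of beta0,
    so Brent root finding on a wide bracket converges. With all effects
    zero this reduces to logit(target).

    beta0 is a property of the population model, so the Monte-Carlo seed is
    derived from the config itself unless overridden; results are cached
    per (config, n_mc, seed).
    """
    target = config.target_prevalence
    if all(all(v == 0.0 for v in c.logodds) for c in config.covariates):
        return float(logit(target))
    if seed is None:
        seed = zlib.crc32(config.model_hash().encode())
    key = (config.model_hash(), int(n_mc), int(seed))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    covs = _sample_covariates(config, seed=zlib.crc32(b"calibration") ^ int(seed) % (2**31), n=n_mc)
    eta = _linear_predictor(config, covs)

    def f(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - target

    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError("target prevalence unreachable for these effects")
    b0 = brentq(f, lo, hi, xtol=1e-10)
    if abs(f(b0)) > tol:
        raise CalibrationError("intercept calibration did not reach tolerance")
    _CALIBRATION_CACHE[key] = float(b0)
    return float(b0)


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    calibration_mc: int = 200_000,
) -> pd.DataFrame:
    """Draw one cohort: covariates, random markers, outcome.

    Fully reproducible: the same config and seed give an identical table.
    Columns: ``subject_id``, one categorical column per covariate, one
    numeric column per random marker, and binary ``outcome``.
    """
    if config is None:
        config = default_config()
    n = config.n
    covs = _sample_covariates(config, seed, n)
    eta = _linear_predictor(config, covs)
    b0 = calibrate_intercept(config, n_mc=calibration_mc)
    risk = expit(b0 + eta)
    out_rng = _column_rng(seed, "outcome")
    outcome = out_rng.binomial(1, risk)

    df = pd.DataFrame({"subject_id": np.arange(1, n + 1)})
    df = pd.concat([df, covs], axis=1)
    for marker in config.random_markers:
        rng = _column_rng(seed, f"marker:{marker.name}")
        df[marker.name] = marker.sample(n, rng)
    df["outcome"] = outcome
    return df
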