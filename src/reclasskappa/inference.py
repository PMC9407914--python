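"""Standard errors, confidence intervals and tests for reclassification
Kappa and NRI.

The asymptotic kappa variance is the Fleiss-Cohen-Everitt large-sample
form evaluated on the 3x3 augmented table (hidden middle column); the test
of kappa = 0 uses the corresponding null variance. The NRI variance is the
standard binomial decomposition over events and non-events:

    var(NRI) = [p_up|D + p_down|D - (p_up|D - p_down|D)^2] / n_D
             + [p_down|ND + p_up|ND - (p_down|ND - p_up|ND)^2] / n_ND

A stratified bootstrap (resampling subjects with replacement within each
outcome class) is available as a reference method for both statistics.
Degenerate tables — no movement at all — report estimate 0 with a
not-available (NaN) p-value rather than a spurious 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    DegenerateDataError,
    ExpectedTable,
    ReclassTable,
    kappa_reclass,
    nri,
)

__all__ = ["IntervalEstimate", "NriIntervals", "kappa_interval", "nri_interval"]


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with SE, CI and two-sided p-value.

    ``p_value`` is NaN ("not available") when the statistic is degenerate:
    with no up/down movement there is nothing to test.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    level: float = 0.95
    method: str = "asymptotic"
    n_boot: int | None = None
    seed: int | None = None

    @property
    def significant(self) -> bool:
        return (not math.isnan(self.p_value)) and self.p_value < 1 - self.level

    def to_dict(self) -> dict:
        d = {
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": None if math.isnan(self.p_value) else self.p_value,
            "level": self.level,
            "method": self.method,
        }
        if self.method == "bootstrap":
            d["n_boot"] = self.n_boot
            d["seed"] = self.seed
        return d


@dataclass(frozen=True)
class NriIntervals:
    down: IntervalEstimate
    up: IntervalEstimate
    total: IntervalEstimate

    def to_dict(self) -> dict:
        return {k: getattr(self, k).to_dict() for k in ("down", "up", "total")}


def _augmented_props(obs: ReclassTable) -> tuple[np.ndarray, int]:
    n = obs.n
    if n == 0:
        raise DegenerateDataError("empty table")
    return obs.augmented() / n, n


def _kappa_variances(obs: ReclassTable) -> tuple[float, float, float]:
    """(kappa, var under alternative, var under the null kappa=0).

    Fleiss, Cohen & Everitt large-sample forms on the augmented square
    table with proportions p_ij, marginals p_i. (rows) and p_.j (columns).
    """
    p, n = _augmented_props(obs)
    prow = p.sum(axis=1)
    pcol = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(prow @ pcol)
    if pe >= 1.0:
        return float("nan"), float("nan"), float("nan")
    kap = (po - pe) / (1 - pe)

    # non-null variance
    diag = np.diag(p)
    term1 = float(np.sum(diag * (1 - (prow + pcol) * (1 - kap)) ** 2))
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    # sum_{i != j} p_ij (p_.i + p_j.)^2  — note the transposed marginals
    w = (pcol[:, None] + prow[None, :]) ** 2  # w[i, j] = (p_.i + p_j.)^2
    term2 = float((1 - kap) ** 2 * np.sum(off * w))
    term3 = (kap - pe * (1 - kap)) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 2)

    # variance under the null hypothesis kappa = 0
    var0 = (pe + pe**2 - float(np.sum(prow * pcol * (prow + pcol)))) / (
        n * (1 - pe) ** 2
    )
    return kap, max(var, 0.0), max(var0, 0.0)


def _wald_interval(est: float, se: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2)
    return est - z * se, est + z * se


def _boot_tables(obs: ReclassTable, B: int, rng: np.random.Generator) -> np.ndarray:
    """Resample direction counts within each outcome column.

    A subject is fully characterised by (direction, outcome), so resampling
    subjects with replacement stratified by outcome is a pair of multinomial
    draws over the direction distribution of each column. Returns an array
    of shape (B, 3, 2) of counts.
    """
    nh, nd = obs.n_healthy, obs.n_diseased
    ph = np.array([obs.a, obs.c, obs.e]) / nh
    pd_ = np.array([obs.b, obs.d, obs.f]) / nd
    healthy = rng.multinomial(nh, ph, size=B)
    diseased = rng.multinomial(nd, pd_, size=B)
    return np.stack([healthy, diseased], axis=2)


def _boot_pvalue(boots: np.ndarray) -> float:
    """Two-sided p from the bootstrap distribution's sign agreement with 0."""
    B = boots.size
    p_low = (np.sum(boots <= 0) + 1) / (B + 1)
    p_high = (np.sum(boots >= 0) + 1) / (B + 1)
    return min(1.0, 2 * min(p_low, p_high))


def kappa_interval(
    obs: ReclassTable,
    exp: ExpectedTable | None = None,
    level: float = 0.95,
    method: str = "asymptotic",
    n_boot: int = 2000,
    seed: int | None = None,
) -> IntervalEstimate:
    """CI and test for the reclassification Kappa.

    ``method='asymptotic'`` uses the large-sample kappa variance (Wald CI
    clipped to [-1, 1]; z-test of kappa=0 with the null variance).
    ``method='bootstrap'`` resamples subjects stratified by outcome and
    reports a percentile CI; the bootstrap seed and replicate count are
    recorded in the result.
    """
    if exp is None:
        exp = ExpectedTable.from_observed(obs)
    kap = kappa_reclass(obs, exp)
    degenerate = obs.row_down == 0 and obs.row_up == 0
    if degenerate:
        return IntervalEstimate(0.0, 0.0, 0.0, 0.0, float("nan"), level, method)
    if math.isnan(kap):
        return IntervalEstimate(
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            level, method,
        )
    if method == "asymptotic":
        kap_, var, var0 = _kappa_variances(obs)
        se = math.sqrt(var)
        lo, hi = _wald_interval(kap, se, level)
        lo, hi = max(lo, -1.0), min(hi, 1.0)
        if var0 > 0:
            z = kap / math.sqrt(var0)
            p = 2 * stats.norm.sf(abs(z))
        else:
            p = float("nan")
        return IntervalEstimate(kap, se, lo, hi, p, level, "asymptotic")
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    tables = _boot_tables(obs, n_boot, rng)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        t = tables[i]
        bt = ReclassTable(
            a=int(t[0, 0]), b=int(t[0, 1]), c=int(t[1, 0]),
            d=int(t[1, 1]), e=int(t[2, 0]), f=int(t[2, 1]),
        )
        boots[i] = kappa_reclass(bt, ExpectedTable.from_observed(bt))
    boots = boots[np.isfinite(boots)]
    alpha = 1 - level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return IntervalEstimate(
        kap, float(np.std(boots, ddof=1)), float(lo), float(hi),
        _boot_pvalue(boots), level, "bootstrap", n_boot, seed,
    )


def _nri_asymptotic(table: ReclassTable, level: float) -> NriIntervals:
    nd_, nu_, nt_ = nri(table)
    nD, nH = table.n_diseased, table.n_healthy
    p_up_d = table.f / nD
    p_down_d = table.b / nD
    p_down_h = table.a / nH
    p_up_h = table.e / nH
    v_events = (p_up_d + p_down_d - (p_up_d - p_down_d) ** 2) / nD
    v_nonevents = (p_down_h + p_up_h - (p_down_h - p_up_h) ** 2) / nH
    v_events = max(v_events, 0.0)
    v_nonevents = max(v_nonevents, 0.0)

    def _one(est: float, var: float) -> IntervalEstimate:
        se = math.sqrt(var)
        lo, hi = _wald_interval(est, se, level)
        if se > 0:
            p = 2 * stats.norm.sf(abs(est) / se)
        else:
            p = float("nan")
        return IntervalEstimate(est, se, lo, hi, p, level, "asymptotic")

    return NriIntervals(
        down=_one(nd_, v_nonevents),
        up=_one(nu_, v_events),
        total=_one(nt_, v_events + v_nonevents),
    )


def nri_interval(
    table: ReclassTable,
    level: float = 0.95,
    method: str = "asymptotic",
    n_boot: int = 2000,
    seed: int | None = None,
) -> NriIntervals:
    """CIs and tests for NRI_down, NRI_up and total NRI.

    With no movement at all the estimates are 0 with NaN p-values,
    mirroring how zero-movement rows are reported as not available.
    """
    if table.n_healthy == 0 or table.n_diseased == 0:
        raise DegenerateDataError("both outcome classes must be present")
    if table.row_down == 0 and table.row_up == 0:
        na = IntervalEstimate(0.0, 0.0, 0.0, 0.0, float("nan"), level, method)
        return NriIntervals(na, na, na)
    if method == "asymptotic":
        return _nri_asymptotic(table, level)
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    tabs = _boot_tables(table, n_boot, rng)
    nh, ndis = table.n_healthy, table.n_diseased
    downs = (tabs[:, 0, 0] - tabs[:, 2, 0]) / nh
    ups = (tabs[:, 2, 1] - tabs[:, 0, 1]) / ndis
    totals = downs + ups
    nd_, nu_, nt_ = nri(table)
    alpha = 1 - level

    def _one(est: float, boots: np.ndarray) -> IntervalEstimate:
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        return IntervalEstimate(
            est, float(np.std(boots, ddof=1)), float(lo), float(hi),
            _boot_pvalue(boots), level, "bootstrap", n_boot, seed,
        )

    return NriIntervals(_one(nd_, downs), _one(nu_, ups), _one(nt_, totals))
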