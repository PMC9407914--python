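"""Chance-corrected reclassification tables, Kappa and NRI.

When a candidate marker is added to a logistic risk model every subject's
predicted risk moves down, up, or not at all.  Cross-tabulating that
direction against the true outcome gives a 3x2 reclassification table.
The net reclassification improvement (NRI) rewards diseased subjects who
move up and disease-free subjects who move down; it takes no account of
the movement a completely uninformative marker would produce by chance.

The reclassification Kappa corrects for that chance component.  Augmenting
the 3x2 table with a structurally empty "hidden" middle column makes it
square, so Cohen's kappa applies with diagonal (down/disease-free, hidden,
up/diseased):

    kappa = (O - E) / (n - E)

where O = a_O + f_O is the observed number of correct reclassifications,
E = a_E + f_E the number expected under independence of direction and
outcome, and n the sample size.  The excess x = O - E counts subjects
correctly reclassified beyond chance and is identical under three
algebraic decompositions (total, disease-free only, diseased only).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "DOWN",
    "NONE",
    "UP",
    "RiskPair",
    "ReclassRule",
    "ReclassTable",
    "ExpectedTable",
    "ReclassResult",
    "classify_direction",
    "build_tables",
    "nri",
    "x_statistic",
    "kappa_reclass",
    "reclassify",
    "SchemaError",
    "DegenerateDataError",
]

# Direction codes returned by classify_direction.
DOWN, NONE, UP = -1, 0, 1
DIRECTION_LABELS = {DOWN: "down", NONE: "none", UP: "up"}


class SchemaError(ValueError):
    """Input violates the expected schema (bad probabilities, outcomes...)."""


class DegenerateDataError(ValueError):
    """Input cannot support the statistic (e.g. an empty outcome class)."""


class RiskPair(NamedTuple):
    """Predicted risks for one subject under the base and extended model."""

    subject_id: object
    p_base: float
    p_new: float
    outcome: int


@dataclass(frozen=True)
class ReclassRule:
    """Policy that turns a pair of predicted risks into a direction.

    mode
        ``continuous`` — any strict change counts; ``unit`` — only changes
        strictly larger than ``delta`` count; ``categorical`` — only
        crossings of the ``cutpoints`` count.
    delta
        Risk step in probability units (unit mode), e.g. 0.01 for a 1% step.
    cutpoints
        Strictly increasing cut-offs inside (0, 1) (categorical mode).
        A probability equal to a cut-off falls in the lower category.
    tie_tol
        Optional tolerance under which |p_new - p_base| is treated as "no
        change" in continuous mode (default 0: exact ties only).  Exposed
        because refitting a model can leave sub-ulp noise on risks.
    """

    mode: str = "continuous"
    delta: float = 0.01
    cutpoints: tuple[float, ...] = ()
    tie_tol: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "unit", "categorical"):
            raise SchemaError(f"unknown rule mode {self.mode!r}")
        if self.mode == "unit":
            if not (self.delta >= 0 and math.isfinite(self.delta)):
                raise SchemaError("unit rule requires finite delta >= 0")
        if self.mode == "categorical":
            cp = tuple(float(c) for c in self.cutpoints)
            if len(cp) == 0:
                raise SchemaError("categorical rule requires cutpoints")
            if any(not (0.0 < c < 1.0) for c in cp):
                raise SchemaError("cutpoints must lie strictly inside (0, 1)")
            if any(b <= a for a, b in zip(cp, cp[1:])):
                raise SchemaError("cutpoints must be strictly increasing")
            object.__setattr__(self, "cutpoints", cp)
        if self.tie_tol < 0:
            raise SchemaError("tie_tol must be >= 0")

    def to_dict(self) -> dict:
        d = {"mode": self.mode}
        if self.mode == "unit":
            d["delta"] = self.delta
        if self.mode == "categorical":
            d["cutpoints"] = list(self.cutpoints)
        if self.tie_tol:
            d["tie_tol"] = self.tie_tol
        return d


@dataclass(frozen=True)
class ReclassTable:
    """Observed 3x2 counts: direction (down/none/up) x outcome (0/1).

    Cell names follow the down/none/up rows and disease-free/diseased
    columns: a..f read row-wise (a = down & disease-free, b = down &
    diseased, ..., f = up & diseased).  The hidden middle column of the
    square augmented table is identically zero and never stored.
    """

    a: int
    b: int
    c: int
    d: int
    e: int
    f: int

    def __post_init__(self) -> None:
        for name in "abcdef":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise SchemaError(f"count {name} must be a non-negative integer")

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int, e: int, f: int) -> "ReclassTable":
        """Build directly from the six cell counts (e.g. a published table)."""
        return cls(int(a), int(b), int(c), int(d), int(e), int(f))

    @property
    def n_healthy(self) -> int:
        return self.a + self.c + self.e

    @property
    def n_diseased(self) -> int:
        return self.b + self.d + self.f

    @property
    def n(self) -> int:
        return self.n_healthy + self.n_diseased

    @property
    def row_down(self) -> int:
        return self.a + self.b

    @property
    def row_none(self) -> int:
        return self.c + self.d

    @property
    def row_up(self) -> int:
        return self.e + self.f

    def as_array(self) -> np.ndarray:
        """3x2 array, rows down/none/up, columns disease-free/diseased."""
        return np.array([[self.a, self.b], [self.c, self.d], [self.e, self.f]], dtype=float)

    def augmented(self) -> np.ndarray:
        """3x3 square table with the zero hidden column in the middle."""
        z = np.zeros(3)
        arr = self.as_array()
        return np.column_stack([arr[:, 0], z, arr[:, 1]])


@dataclass(frozen=True)
class ExpectedTable:
    """Chance-expected counts: row marginal x column marginal / n."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_observed(cls, obs: ReclassTable) -> "ExpectedTable":
        n = obs.n
        if n == 0:
            raise DegenerateDataError("empty table")
        nh, nd = obs.n_healthy, obs.n_diseased
        return cls(
            a=obs.row_down * nh / n,
            b=obs.row_down * nd / n,
            c=obs.row_none * nh / n,
            d=obs.row_none * nd / n,
            e=obs.row_up * nh / n,
            f=obs.row_up * nd / n,
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d], [self.e, self.f]], dtype=float)


def _round_half_away(v: float) -> int:
    """Round to nearest integer, halves away from zero (clinical convention)."""
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


def _coerce_pairs(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a DataFrame, an iterable of RiskPair, or an array triple."""
    if isinstance(pairs, pd.DataFrame):
        missing = {"p_base", "p_new", "outcome"} - set(pairs.columns)
        if missing:
            raise SchemaError(f"missing columns: {sorted(missing)}")
        p0 = pairs["p_base"].to_numpy(dtype=float)
        p1 = pairs["p_new"].to_numpy(dtype=float)
        y = pairs["outcome"].to_numpy()
    elif isinstance(pairs, tuple) and len(pairs) == 3:
        p0, p1, y = (np.asarray(v) for v in pairs)
        p0 = p0.astype(float)
        p1 = p1.astype(float)
    else:
        rows = list(pairs)
        if not rows:
            raise DegenerateDataError("no subjects")
        p0 = np.array([r.p_base for r in rows], dtype=float)
        p1 = np.array([r.p_new for r in rows], dtype=float)
        y = np.array([r.outcome for r in rows])
    if p0.size == 0:
        raise DegenerateDataError("no subjects")
    _validate_probs(p0)
    _validate_probs(p1)
    y = _validate_outcome(y)
    if not (p0.shape == p1.shape == y.shape):
        raise SchemaError("p_base, p_new and outcome must have equal length")
    return p0, p1, y


def _validate_probs(p: np.ndarray) -> None:
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise SchemaError("predicted risks must be finite and within [0, 1]")


def _validate_outcome(y: np.ndarray) -> np.ndarray:
    yf = np.asarray(y, dtype=float)
    if not np.all(np.isin(yf, (0.0, 1.0))):
        raise SchemaError("outcome must be binary 0/1")
    return yf.astype(np.int8)


def classify_direction(p_base, p_new, rule: ReclassRule):
    """Direction of risk change per subject: -1 (down), 0 (none), +1 (up).

    Vectorised; scalars in, python int out.  Continuous: any strict change
    (beyond ``tie_tol``).  Unit: |change| strictly greater than ``delta``.
    Categorical: sign of the category-index change, where the category of p
    is the number of cutpoints strictly below p.
    """
    scalar = np.isscalar(p_base) and np.isscalar(p_new)
    p0 = np.atleast_1d(np.asarray(p_base, dtype=float))
    p1 = np.atleast_1d(np.asarray(p_new, dtype=float))
    _validate_probs(p0)
    _validate_probs(p1)
    diff = p1 - p0
    if rule.mode == "continuous":
        tol = rule.tie_tol
        d = np.where(diff > tol, UP, np.where(diff < -tol, DOWN, NONE))
    elif rule.mode == "unit":
        d = np.where(diff > rule.delta, UP, np.where(diff < -rule.delta, DOWN, NONE))
    else:
        cuts = np.asarray(rule.cutpoints)
        # category index = number of cutpoints strictly below p; a value at a
        # cut-off stays in the lower category
        k0 = np.searchsorted(cuts, p0, side="left")
        k1 = np.searchsorted(cuts, p1, side="left")
        d = np.sign(k1 - k0).astype(int)
    d = d.astype(np.int8)
    if scalar:
        return int(d[0])
    return d


def build_tables(pairs, rule: ReclassRule) -> tuple[ReclassTable, ExpectedTable]:
    """Tally directions against outcomes and derive the chance-expected table.

    Raises :class:`DegenerateDataError` when either outcome class is empty
    (one NRI component would have a zero denominator).
    """
    p0, p1, y = _coerce_pairs(pairs)
    d = classify_direction(p0, p1, rule)
    if y.min() == y.max():
        raise DegenerateDataError("both outcome classes must be present")
    counts = {}
    for name, drow, col in (
        ("a", DOWN, 0), ("b", DOWN, 1),
        ("c", NONE, 0), ("d", NONE, 1),
        ("e", UP, 0), ("f", UP, 1),
    ):
        counts[name] = int(np.sum((d == drow) & (y == col)))
    obs = ReclassTable(**counts)
    return obs, ExpectedTable.from_observed(obs)


def nri(table: ReclassTable) -> tuple[float, float, float]:
    """Net reclassification improvement (down component, up component, total).

    nri_down = (a - e)/n_healthy rewards disease-free subjects whose risk
    fell; nri_up = (f - b)/n_diseased rewards diseased subjects whose risk
    rose.  Total NRI is their sum and lives in [-2, 2].
    """
    if table.n_healthy == 0 or table.n_diseased == 0:
        raise DegenerateDataError("both outcome classes must be present")
    nri_down = (table.a - table.e) / table.n_healthy
    nri_up = (table.f - table.b) / table.n_diseased
    return nri_down, nri_up, nri_down + nri_up


def x_statistic(obs: ReclassTable, exp: ExpectedTable) -> tuple[float, int]:
    """Correct reclassifications beyond chance: x = O - E.

    Returns the raw value and its integer rounding (half away from zero),
    since expected counts are generally fractional but x counts people.
    """
    x_raw = (obs.a + obs.f) - (exp.a + exp.f)
    return x_raw, _round_half_away(x_raw)


def kappa_reclass(obs: ReclassTable, exp: ExpectedTable) -> float:
    """Reclassification Kappa: (O - E)/(n - E) on the augmented square table.

    Positive kappa means the marker reclassifies better than chance,
    negative worse, zero no change beyond chance.  Returns NaN when n == E
    (every subject is expected to be correctly reclassified by chance, so
    the statistic is undefined / not available).
    """
    O = obs.a + obs.f
    E = exp.a + exp.f
    n = obs.n
    if n == E:
        return float("nan")
    return (O - E) / (n - E)


@dataclass(frozen=True)
class ReclassResult:
    """Complete result of one reclassification analysis."""

    x: int
    x_raw: float
    kappa: float
    nri_down: float
    nri_up: float
    nri: float
    O: float
    E: float
    n: int
    n_healthy: int
    n_diseased: int
    rule: ReclassRule
    observed: ReclassTable
    expected: ExpectedTable

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "x_raw": self.x_raw,
            "kappa": None if math.isnan(self.kappa) else self.kappa,
            "nri_down": self.nri_down,
            "nri_up": self.nri_up,
            "nri": self.nri,
            "O": self.O,
            "E": self.E,
            "n": self.n,
            "n_healthy": self.n_healthy,
            "n_diseased": self.n_diseased,
            "rule": self.rule.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def format_table(self) -> str:
        """Human-readable observed/expected table (hidden column shown)."""
        o, ex = self.observed, self.expected
        rows = [
            ("down", o.a, o.b, ex.a, ex.b),
            ("no change", o.c, o.d, ex.c, ex.d),
            ("up", o.e, o.f, ex.e, ex.f),
        ]
        lines = [
            f"{'':12s}{'observed':>24s}    {'expected':>24s}",
            f"{'direction':12s}{'dis-free':>10s}{'hidden':>4s}{'diseased':>10s}"
            f"    {'dis-free':>10s}{'hidden':>4s}{'diseased':>10s}",
        ]
        for name, ao, bo, ae, be in rows:
            lines.append(
                f"{name:12s}{ao:10d}{0:4d}{bo:10d}    {ae:10.2f}{0:4d}{be:10.2f}"
            )
        lines.append(
            f"{'total':12s}{self.n_healthy:10d}{0:4d}{self.n_diseased:10d}"
            f"    n = {self.n}"
        )
        kap = "NA" if math.isnan(self.kappa) else f"{self.kappa:.4f}"
        lines.append(
            f"O = {self.O:g}, E = {self.E:g}, x = {self.x} ({100 * self.x / self.n:.2f}% of n)"
        )
        lines.append(
            f"kappa = {kap}; NRI_down = {self.nri_down:.4f}, "
            f"NRI_up = {self.nri_up:.4f}, NRI = {self.nri:.4f}"
        )
        return "\n".join(lines)


def reclassify(pairs, rule: ReclassRule) -> ReclassResult:
    """Run the full pipeline: tables, x, kappa and NRI, in one call.

    The result is invariant under any permutation of the subjects.
    """
    obs, exp = build_tables(pairs, rule)
    return result_from_tables(obs, exp, rule)


def result_from_tables(
    obs: ReclassTable, exp: ExpectedTable | None = None, rule: ReclassRule | None = None
) -> ReclassResult:
    """Assemble a ReclassResult from a (possibly hand-entered) table."""
    if exp is None:
        exp = ExpectedTable.from_observed(obs)
    if rule is None:
        rule = ReclassRule("continuous")
    x_raw, x = x_statistic(obs, exp)
    kap = kappa_reclass(obs, exp)
    nd, nu, nt = nri(obs)
    return ReclassResult(
        x=x,
        x_raw=x_raw,
        kappa=kap,
        nri_down=nd,
        nri_up=nu,
        nri=nt,
        O=float(obs.a + obs.f),
        E=exp.a + exp.f,
        n=obs.n,
        n_healthy=obs.n_healthy,
        n_diseased=obs.n_diseased,
        rule=rule,
        observed=obs,
        expected=exp,
    )
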