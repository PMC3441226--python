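"""Pairwise Pearson correlation with significance, Bonferroni correction,
and r-value-ranked coexpression lists.

For a pair of probe-set profiles the chain is::

    r  ->  t = r * sqrt(n - 2) / sqrt(1 - r^2)   (nu = n - 2 d.o.f.)
       ->  p = two-sided Student tail probability of |t|
       ->  e = min(n_tests * p, 1)               (Bonferroni)

``n_tests`` defaults to the number of unordered probe pairs in the screen,
m * (m - 1) / 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from hgca.errors import ProbeLookupError, ValidationError
from hgca.matrix_io import ExpressionMatrix, ProbeSetId

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValidationError):
    """A profile is constant, so its correlation is undefined."""


@dataclass(frozen=True)
class CorrelationRecord:
    """One probe-set pair with its full statistics chain."""

    probe_x: ProbeSetId
    probe_y: ProbeSetId
    r: float
    t: float
    p: float
    e: float
    n: int

    @property
    def nu(self) -> int:
        return self.n - 2

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValidationError(f"|r| > 1: {self.r}")
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.e <= 1.0):
            raise ValidationError("p and e must lie in [0, 1]")
        if self.n < 3:
            raise ValidationError("need n >= 3 samples")


@dataclass
class CorrelationMatrix:
    """Symmetric all-against-all r-value matrix over probe sets."""

    probe_ids: list[ProbeSetId]
    R: np.ndarray
    n_samples: int | None = None
    excluded_probes: tuple[ProbeSetId, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.probe_ids = [ProbeSetId(p) for p in self.probe_ids]
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.probe_ids)
        if self.R.shape != (m, m):
            raise ValidationError("R shape does not match probe_ids")
        if m and not np.allclose(self.R, self.R.T, atol=1e-9):
            raise ValidationError("R is not symmetric")
        if m and not np.allclose(np.diag(self.R), 1.0, atol=1e-9):
            raise ValidationError("R diagonal is not 1")
        if m and np.any(np.abs(self.R) > 1 + 1e-9):
            raise ValidationError("R has entries outside [-1, 1]")

    def probe_index(self, probe: str) -> int:
        try:
            return self.probe_ids.index(ProbeSetId(probe))
        except ValueError:
            raise ProbeLookupError(probe) from None

    def r(self, probe_x: str, probe_y: str) -> float:
        return float(self.R[self.probe_index(probe_x), self.probe_index(probe_y)])


def _validate_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("x has zero variance")
    if np.ptp(y) == 0:
        raise ZeroVarianceError("y has zero variance")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation: covariance over the product of standard
    deviations."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    _validate_pair(xa, ya)
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    r = float(np.dot(dx, dy) / math.sqrt(np.dot(dx, dx) * np.dot(dy, dy)))
    return max(-1.0, min(1.0, r))


def pearson_r_standardized(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation as the mean cross-product of the standardized
    variables — algebraically identical to :func:`pearson_r`; kept as an
    explicit second route and cross-checked in the test suite."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    _validate_pair(xa, ya)
    zx = (xa - xa.mean()) / xa.std()
    zy = (ya - ya.mean()) / ya.std()
    r = float(np.sum(zx * zy) / xa.size)
    return max(-1.0, min(1.0, r))


def t_statistic(r: float, n: int) -> float:
    """t = r * sqrt(n - 2) / sqrt(1 - r^2); +-inf when |r| = 1."""
    if n < 3:
        raise ValidationError("need n >= 3 samples")
    if abs(r) > 1 + 1e-12:
        raise ValidationError(f"|r| > 1: {r}")
    if abs(r) >= 1.0:
        return math.copysign(math.inf, r)
    return r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)


def p_two_sided(t: float, nu: int) -> float:
    """Two-sided Student-t tail probability P(|T| >= |t|) at nu d.o.f."""
    if nu < 1:
        raise ValidationError("nu must be >= 1")
    if math.isinf(t):
        return 0.0
    return float(2.0 * stats.t.sf(abs(t), df=nu))


def bonferroni(p: float, n_tests: int) -> float:
    """e = min(n_tests * p, 1)."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError("p must lie in [0, 1]")
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return min(n_tests * p, 1.0)


def default_n_tests(n_probes: int) -> int:
    """Bonferroni family size of an all-against-all screen over *n_probes*."""
    return max(1, n_probes * (n_probes - 1) // 2)


def make_record(
    probe_x: str, probe_y: str, r: float, n: int, n_tests: int
) -> CorrelationRecord:
    t = t_statistic(r, n)
    p = p_two_sided(t, n - 2)
    e = bonferroni(p, n_tests)
    return CorrelationRecord(ProbeSetId(probe_x), ProbeSetId(probe_y), r, t, p, e, n)


def correlation_matrix(matrix: ExpressionMatrix) -> CorrelationMatrix:
    """All-against-all Pearson correlation of the probe rows.

    Zero-variance (constant) rows have undefined correlations; they are
    excluded from the result, logged, and listed in
    :attr:`CorrelationMatrix.excluded_probes`.
    """
    if matrix.n_probes < 2:
        raise ValidationError("need at least 2 probe sets")
    if matrix.n_samples < 3:
        raise ValidationError("need at least 3 samples")
    variances = matrix.values.var(axis=1)
    keep = variances > 0
    excluded = tuple(p for p, ok in zip(matrix.probe_ids, keep) if not ok)
    if excluded:
        logger.warning(
            "excluding %d zero-variance probe set(s): %s",
            len(excluded),
            ", ".join(excluded),
        )
    values = matrix.values[keep]
    probe_ids = [p for p, ok in zip(matrix.probe_ids, keep) if ok]
    if len(probe_ids) < 2:
        raise ValidationError("fewer than 2 probe sets with nonzero variance")
    R = np.corrcoef(values)
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    return CorrelationMatrix(probe_ids, R, n_samples=matrix.n_samples, excluded_probes=excluded)


def correlation_records(
    matrix: ExpressionMatrix, n_tests: int | None = None
) -> list[CorrelationRecord]:
    """Full statistics for every unordered probe pair of *matrix*."""
    cm = correlation_matrix(matrix)
    m = len(cm.probe_ids)
    if n_tests is None:
        n_tests = default_n_tests(m)
    records = []
    for i in range(m):
        for j in range(i + 1, m):
            records.append(
                make_record(
                    cm.probe_ids[i], cm.probe_ids[j], float(cm.R[i, j]),
                    cm.n_samples, n_tests,
                )
            )
    return records


def ranked_list(
    query: str,
    cm: CorrelationMatrix,
    k: int,
    direction: Literal["correlated", "anticorrelated"] = "correlated",
    n_tests: int | None = None,
) -> list[CorrelationRecord]:
    """Top-*k* coexpression partners of *query*, excluding the self-pair.

    ``direction="correlated"`` ranks by descending r, ``"anticorrelated"`` by
    ascending r; ties are broken by probe ID.  Each entry carries the full
    statistics chain when the matrix knows its sample count.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if direction not in ("correlated", "anticorrelated"):
        raise ValidationError(f"unknown direction: {direction!r}")
    qi = cm.probe_index(query)
    if n_tests is None:
        n_tests = default_n_tests(len(cm.probe_ids))
    sign = -1.0 if direction == "correlated" else 1.0
    candidates = sorted(
        ((i, p) for i, p in enumerate(cm.probe_ids) if i != qi),
        key=lambda ip: (sign * cm.R[qi, ip[0]], ip[1]),
    )
    n = cm.n_samples if cm.n_samples is not None else 3
    return [
        make_record(cm.probe_ids[qi], p, float(cm.R[qi, i]), n, n_tests)
        for i, p in candidates[:k]
    ]
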