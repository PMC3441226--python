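"""Annotation-term over-representation on a coexpression list.

For a term present in ``m`` of the ``n`` catalogued probe sets and in ``k``
members of a list of size ``c``, the raw significance is the hypergeometric
upper tail P(X >= k).  All terms tested within a category are then
Benjamini-Hochberg corrected, and records are trimmed at an adjusted-p
cutoff (default 0.05).

Free-text categories (gene names, descriptions) are tokenized into
uppercase words; structured categories (GO, EC, OMIM, pathway, InterPro,
TransFac) are matched as whole terms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from hgca.errors import ValidationError
from hgca.matrix_io import AnnotationCatalog

#: Categories whose annotation strings are free text and get tokenized.
TEXT_CATEGORIES = frozenset({"gene_name", "description"})

#: Minimal English stop list; single letters and two-letter fragments are
#: already dropped by the length rule.
STOPWORDS = frozenset(
    {
        "AND", "THE", "FOR", "WITH", "FROM", "THAT", "THIS", "ARE", "WAS",
        "NOT", "HAS", "HAVE", "ITS", "VIA", "INTO", "ALSO", "MAY", "BEEN",
        "BUT", "ALL", "ANY", "PER", "NON",
    }
)

_MIN_TOKEN_LENGTH = 3
_TOKEN_SPLIT = re.compile(r"[^0-9A-Za-z]+")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term with its contingency counts and significance."""

    term: str
    category: str
    n: int  # catalogued probe sets (universe)
    m: int  # universe probe sets carrying the term
    c: int  # query list size
    k: int  # list probe sets carrying the term
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.c, self.m) and self.m <= self.n and self.c <= self.n):
            raise ValidationError(
                f"inconsistent counts n={self.n} m={self.m} c={self.c} k={self.k}"
            )
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adj <= 1.0):
            raise ValidationError("p-values must lie in [0, 1]")


def tokenize(text: str) -> set[str]:
    """Uppercase alphanumeric tokens of *text*, dropping tokens shorter than
    3 characters, bare numerals, and stop-words."""
    tokens = _TOKEN_SPLIT.split(text.upper())
    return {
        t
        for t in tokens
        if len(t) >= _MIN_TOKEN_LENGTH and not t.isdigit() and t not in STOPWORDS
    }


def hypergeom_upper(n: int, m: int, c: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts term-carrying probe sets in a size-``c`` draw (without
    replacement) from ``n`` probe sets of which ``m`` carry the term.
    Delegates to scipy's log-space survival function; equivalently
    1 - P(X <= k - 1).
    """
    if not (0 <= m <= n and 0 <= c <= n):
        raise ValidationError(f"need 0 <= m, c <= n; got n={n} m={m} c={c}")
    if not (0 <= k <= min(c, m)):
        raise ValidationError(f"need 0 <= k <= min(c, m); got k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n, m, c))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j >= i} (M * p_(j) / j), capped at 1, where p_(j) is the
    j-th smallest raw p and M the family size.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    M = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * M / np.arange(1, M + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(adjusted, 0.0, 1.0, out=adjusted)
    out = np.empty(M)
    out[order] = adjusted
    return [float(v) for v in out]


def _term_sets(catalog: AnnotationCatalog, category: str) -> dict[str, frozenset[str]]:
    tokenized = category in TEXT_CATEGORIES
    result = {}
    for probe in catalog.entries:
        raw = catalog.terms(probe, category)
        if tokenized:
            terms: set[str] = set()
            for annotation in raw:
                terms |= tokenize(annotation)
            result[probe] = frozenset(terms)
        else:
            result[probe] = raw
    return result


def enrich(
    probe_list: Sequence[str],
    catalog: AnnotationCatalog,
    category: str,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Over-represented terms of *category* in *probe_list*.

    The universe is the set of catalogued probe sets.  One record per term
    occurring in the list; BH correction spans all terms tested in the
    category; records with adjusted p <= *alpha* are returned sorted by
    ascending adjusted p (ties by term).
    """
    if not probe_list:
        raise ValidationError("probe list is empty")
    if len(set(probe_list)) != len(probe_list):
        raise ValidationError("probe list contains duplicates")
    if not catalog.entries:
        raise ValidationError("annotation catalog is empty")
    missing = [p for p in probe_list if p not in catalog.entries]
    if missing:
        raise ValidationError(
            f"probe set(s) absent from the annotation catalog: {', '.join(missing)}"
        )
    term_sets = _term_sets(catalog, category)
    n = len(term_sets)
    c = len(probe_list)

    list_terms: set[str] = set()
    for probe in probe_list:
        list_terms |= term_sets[probe]
    if not list_terms:
        return []

    m_counts = {t: 0 for t in list_terms}
    for terms in term_sets.values():
        for t in terms & list_terms:
            m_counts[t] += 1
    k_counts = {t: 0 for t in list_terms}
    for probe in probe_list:
        for t in term_sets[probe] & list_terms:
            k_counts[t] += 1

    terms = sorted(list_terms)
    raw = [hypergeom_upper(n, m_counts[t], c, k_counts[t]) for t in terms]
    adjusted = bh_adjust(raw)
    records = [
        EnrichmentRecord(t, category, n, m_counts[t], c, k_counts[t], p, q)
        for t, p, q in zip(terms, raw, adjusted)
        if q <= alpha
    ]
    records.sort(key=lambda rec: (rec.p_adj, rec.term))
    return records
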