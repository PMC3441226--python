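"""Quality control, duplicate removal, balanced sample selection, and
per-sample trimmed-mean signal normalization.

Normalization follows the standard Affymetrix per-chip procedure: for each
sample the top and bottom 2% of signal order statistics are removed, a factor
is computed that brings the mean of the remaining 96% to 500, every value is
multiplied by that factor, and the result is rounded to the nearest 0.5.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from hgca.errors import ValidationError
from hgca.matrix_io import ExpressionMatrix

#: Raw probe intensities are 16-bit scanner values.
INTENSITY_MIN = 0.0
INTENSITY_MAX = 65535.0

SIGNATURE_LENGTH = 32 + 40 + 8  # MD5 + SHA-1 + CRC32 hex digits


@dataclass
class IntensityVector:
    """Raw probe intensities of one microarray sample."""

    sample_id: str
    values: Sequence[float]
    tissue: str = ""
    series: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        self.values = [float(v) for v in self.values]


def qc_intensity_range(vector: IntensityVector) -> tuple[bool, list[int]]:
    """Check that every intensity lies inside [0, 65535] inclusive.

    Returns ``(passed, offending_indices)``; an empty vector is invalid.
    """
    if not vector.values:
        raise ValidationError(f"{vector.sample_id}: empty intensity vector")
    bad = [
        i
        for i, v in enumerate(vector.values)
        if not (INTENSITY_MIN <= v <= INTENSITY_MAX)
    ]
    return (not bad, bad)


def serialize_intensities(values: Iterable[float]) -> str:
    """Canonical string form of an intensity vector before hashing.

    Each value is rendered as its shortest exact decimal (integral values
    without a trailing ``.0``) and the renderings are concatenated with no
    separator.
    """
    parts = []
    for v in values:
        f = float(v)
        parts.append(str(int(f)) if f.is_integer() else repr(f))
    return "".join(parts)


def intensity_signature(vector: IntensityVector) -> str:
    """80-hex-character signature: MD5 + SHA-1 + zero-padded CRC32 of the
    canonical serialization, concatenated in that order."""
    data = serialize_intensities(vector.values).encode("ascii")
    md5 = hashlib.md5(data).hexdigest()
    sha1 = hashlib.sha1(data).hexdigest()
    crc = format(zlib.crc32(data) & 0xFFFFFFFF, "08x")
    signature = md5 + sha1 + crc
    assert len(signature) == SIGNATURE_LENGTH
    return signature


def deduplicate(
    samples: Sequence[IntensityVector],
) -> tuple[list[IntensityVector], dict[str, list[str]]]:
    """Collapse samples with identical intensity signatures.

    Keeps, per signature, the sample with the lexicographically smallest ID.
    Returns the retained samples (sorted by sample ID) and a report mapping
    each signature to all member sample IDs.
    """
    groups: dict[str, list[IntensityVector]] = {}
    for sample in samples:
        groups.setdefault(intensity_signature(sample), []).append(sample)
    unique: list[IntensityVector] = []
    report: dict[str, list[str]] = {}
    for signature, members in groups.items():
        members = sorted(members, key=lambda s: s.sample_id)
        unique.append(members[0])
        report[signature] = [s.sample_id for s in members]
    unique.sort(key=lambda s: s.sample_id)
    return unique, report


def balanced_selection(
    samples: Sequence[IntensityVector], target_n: int
) -> list[str]:
    """Select ``min(target_n, len(samples))`` sample IDs as evenly as possible
    across tissues and, within each tissue, across series.

    Deterministic round-robin: repeatedly draw from the tissue with the
    fewest selected samples (ties by tissue name), and within it from the
    series with the fewest selected (ties by series name); within a series
    IDs are taken in lexicographic order.  The result is invariant to the
    input order of *samples*.
    """
    if target_n < 1:
        raise ValidationError("target_n must be >= 1")
    pools: dict[str, dict[str, list[str]]] = {}
    for sample in sorted(samples, key=lambda s: (s.tissue, s.series, s.sample_id)):
        pools.setdefault(sample.tissue, {}).setdefault(sample.series, []).append(
            sample.sample_id
        )
    # lists are sorted ascending; consume from the front
    tissue_counts = {t: 0 for t in pools}
    series_counts = {t: {s: 0 for s in pools[t]} for t in pools}
    selected: list[str] = []
    total = sum(len(ids) for by_series in pools.values() for ids in by_series.values())
    target = min(target_n, total)
    while len(selected) < target:
        open_tissues = [t for t in pools if any(pools[t].values())]
        tissue = min(open_tissues, key=lambda t: (tissue_counts[t], t))
        open_series = [s for s in pools[tissue] if pools[tissue][s]]
        series = min(open_series, key=lambda s: (series_counts[tissue][s], s))
        selected.append(pools[tissue][series].pop(0))
        tissue_counts[tissue] += 1
        series_counts[tissue][series] += 1
    return selected


def drop_control_probesets(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove AFFX-prefixed control probe sets, preserving row order."""
    keep = [i for i, p in enumerate(matrix.probe_ids) if not p.is_control]
    if not keep:
        raise ValidationError("all probe sets are AFFX controls; nothing left to analyse")
    if len(keep) == matrix.n_probes:
        return matrix
    return ExpressionMatrix(
        [matrix.probe_ids[i] for i in keep],
        list(matrix.sample_ids),
        matrix.values[keep, :],
        matrix.sample_meta,
    )


def scaling_factor(
    sample_values: Sequence[float], trim_fraction: float = 0.02, target: float = 500.0
) -> float:
    """Per-sample scaling factor: ``target`` divided by the trimmed mean.

    The trim removes the ``floor(trim_fraction * N)`` highest and lowest order
    statistics (ties broken by order statistic, not value identity).
    """
    values = np.asarray(sample_values, dtype=float)
    if not (0.0 <= trim_fraction < 0.5):
        raise ValidationError("trim_fraction must lie in [0, 0.5)")
    n = values.size
    k = int(np.floor(trim_fraction * n))
    trimmed = np.sort(values)[k : n - k]
    if trimmed.size < 3:
        raise ValidationError(f"need >= 3 values after trimming, have {trimmed.size}")
    mean = float(trimmed.mean())
    if mean == 0.0:
        raise ValidationError("trimmed mean is zero; scaling factor undefined")
    return target / mean


def trimmed_mean(sample_values: Sequence[float], trim_fraction: float = 0.02) -> float:
    """Mean of the values with the top/bottom ``floor(trim_fraction*N)`` order
    statistics removed (the quantity :func:`scaling_factor` drives to target)."""
    values = np.sort(np.asarray(sample_values, dtype=float))
    k = int(np.floor(trim_fraction * values.size))
    trimmed = values[k : values.size - k]
    if trimmed.size == 0:
        raise ValidationError("trim removes every value")
    return float(trimmed.mean())


def round_to_half(x):
    """Round to the nearest multiple of 0.5; exact midpoints round away from
    zero (half-up for the non-negative signals used here)."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("cannot round non-finite values")
    rounded = np.sign(arr) * np.floor(np.abs(arr) * 2.0 + 0.5) / 2.0
    rounded = rounded + 0.0  # normalize -0.0
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(rounded)
    return rounded


def normalize_matrix(
    matrix: ExpressionMatrix, trim_fraction: float = 0.02, target: float = 500.0
) -> ExpressionMatrix:
    """Apply trimmed-mean scaling then half-unit rounding to every sample
    (column) independently.  Control probe sets must already be dropped."""
    values = matrix.values.copy()
    for j in range(matrix.n_samples):
        factor = scaling_factor(values[:, j], trim_fraction=trim_fraction, target=target)
        values[:, j] = round_to_half(values[:, j] * factor)
    return ExpressionMatrix(
        list(matrix.probe_ids), list(matrix.sample_ids), values, matrix.sample_meta
    )
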