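"""Deterministic synthetic data with recorded ground truth.

Everything the pipeline consumes can be generated here without downloads:
expression matrices with planted coexpression modules, annotation catalogs
with planted enriched terms, raw intensity vectors with planted duplicates,
and promoter sequences with planted motif sites.  Every generator is a pure
function of its spec (seed included).

Coexpression modules use a latent-factor model: member profiles are
``sqrt(rho) * f + sqrt(1 - rho) * eps`` for a shared per-sample factor *f*,
so the expected within-module Pearson correlation is exactly ``rho``
(latent_strength).  Signals are affinely mapped to a positive MAS5-like
scale, which leaves Pearson correlations unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from hgca.errors import ValidationError
from hgca.matrix_io import AnnotationCatalog, ExpressionMatrix
from hgca.preprocess import INTENSITY_MAX, IntensityVector
from hgca.pwm_scan import BASES, Pwm

_SIGNAL_CENTER = 500.0
_SIGNAL_SCALE = 80.0


@dataclass(frozen=True)
class ModuleSpec:
    """One planted coexpression module."""

    size: int
    latent_strength: float
    term: str

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError("module size must be >= 1")
        if not (0.0 < self.latent_strength < 1.0):
            raise ValidationError("latent_strength must lie in (0, 1)")


@dataclass(frozen=True)
class TissueSpec:
    """A tissue with the number of samples in each of its series."""

    name: str
    series_counts: tuple[int, ...]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic data set."""

    n_probes: int = 50
    n_samples: int = 100
    modules: Sequence[ModuleSpec] = field(default_factory=tuple)
    noise_sd: float = 1.0
    seed: int = 0
    duplicates: int = 0
    tissues: Sequence[TissueSpec] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.modules = tuple(self.modules)
        self.tissues = tuple(self.tissues)
        if self.n_probes < 1 or self.n_samples < 1:
            raise ValidationError("n_probes and n_samples must be >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.duplicates < 0:
            raise ValidationError("duplicates must be >= 0")
        if sum(m.size for m in self.modules) > self.n_probes:
            raise ValidationError("module sizes exceed n_probes")


def _sample_labels(spec: FixtureSpec, count: int) -> list[tuple[str, str]]:
    """(tissue, series) label per sample, cycling through the tissue spec."""
    slots: list[tuple[str, str]] = []
    for tissue in spec.tissues:
        for s_idx, s_count in enumerate(tissue.series_counts, start=1):
            slots.extend((tissue.name, f"{tissue.name}_GSE{s_idx}") for _ in range(s_count))
    if not slots:
        slots = [("", "")]
    return [slots[i % len(slots)] for i in range(count)]


def make_expression(spec: FixtureSpec) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Expression matrix with planted modules plus the ground-truth map
    ``term -> member probe IDs``."""
    rng = np.random.default_rng(spec.seed)
    raw = rng.normal(size=(spec.n_probes, spec.n_samples))
    probe_ids = [f"PS{i:05d}_at" for i in range(1, spec.n_probes + 1)]
    module_map: dict[str, list[str]] = {}
    row = 0
    for module in spec.modules:
        factor = rng.normal(size=spec.n_samples)
        lam = np.sqrt(module.latent_strength)
        sd = np.sqrt(1.0 - module.latent_strength)
        members = []
        for _ in range(module.size):
            raw[row] = lam * factor + sd * raw[row]
            members.append(probe_ids[row])
            row += 1
        module_map[module.term] = members
    values = np.clip(_SIGNAL_CENTER + _SIGNAL_SCALE * spec.noise_sd * raw, 0.0, None)
    sample_ids = [f"GSM{i:05d}" for i in range(1, spec.n_samples + 1)]
    labels = _sample_labels(spec, spec.n_samples)
    meta = {
        sid: {"tissue": tissue, "series": series}
        for sid, (tissue, series) in zip(sample_ids, labels)
    }
    return ExpressionMatrix(probe_ids, sample_ids, values, meta), module_map


def make_catalog(
    spec: FixtureSpec,
    module_map: dict[str, list[str]],
    category: str = "go_bp",
    n_background_terms: int = 20,
    background_rate: float = 0.05,
) -> AnnotationCatalog:
    """Catalog in which each module's members share the module term and
    background terms are sprinkled independently at *background_rate*.

    Every probe set is registered, so the enrichment universe equals
    ``spec.n_probes``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    catalog = AnnotationCatalog()
    probe_ids = [f"PS{i:05d}_at" for i in range(1, spec.n_probes + 1)]
    for probe in probe_ids:
        catalog.add(probe, category)  # register with an empty term set
    for term, members in module_map.items():
        for probe in members:
            catalog.add(probe, category, term)
    for b in range(1, n_background_terms + 1):
        mask = rng.random(spec.n_probes) < background_rate
        for probe, hit in zip(probe_ids, mask):
            if hit:
                catalog.add(probe, category, f"BG{b:03d}")
    return catalog


def make_intensity_set(spec: FixtureSpec, n_values: int = 64) -> list[IntensityVector]:
    """Intensity vectors with exactly ``spec.duplicates`` planted copies.

    Base samples get distinct random vectors (tissue/series labels cycle
    through the tissue spec); each planted duplicate copies an earlier base
    sample's values under a fresh sample ID, so deduplication must remove
    exactly ``spec.duplicates`` samples.
    """
    base_n = sum(c for t in spec.tissues for c in t.series_counts) or spec.n_samples
    rng = np.random.default_rng(spec.seed + 2)
    labels = _sample_labels(spec, base_n)
    samples = []
    for i in range(base_n):
        values = rng.integers(0, int(INTENSITY_MAX) + 1, size=n_values).astype(float)
        values[0] = i  # guarantees pairwise-distinct base vectors
        tissue, series = labels[i]
        samples.append(
            IntensityVector(f"GSM{i + 1:05d}", values.tolist(), tissue=tissue, series=series)
        )
    for d in range(spec.duplicates):
        source = samples[d % base_n]
        samples.append(
            IntensityVector(
                f"GSM{base_n + d + 1:05d}",
                list(source.values),
                tissue=source.tissue,
                series=source.series,
            )
        )
    return samples


def make_promoters(
    pwm: Pwm,
    n: int,
    site_rate: float,
    seed: int,
    length: int = 500,
) -> tuple[list[tuple[str, str]], list[tuple[str, int]]]:
    """Random promoter sequences with the matrix consensus planted at
    recorded plus-strand offsets.

    Returns ``(records, truth)`` where records are ``(id, sequence)`` pairs
    and truth lists ``(id, offset)`` for every planted site.
    """
    if not (0.0 <= site_rate <= 1.0):
        raise ValidationError("site_rate must lie in [0, 1]")
    if length < len(pwm):
        raise ValidationError("promoter length shorter than the matrix")
    rng = np.random.default_rng(seed)
    consensus = pwm.consensus
    records: list[tuple[str, str]] = []
    truth: list[tuple[str, int]] = []
    for i in range(1, n + 1):
        seq = rng.choice(list(BASES), size=length)
        seq_id = f"promoter_{i:04d}"
        if rng.random() < site_rate:
            offset = int(rng.integers(0, length - len(pwm) + 1))
            seq[offset : offset + len(pwm)] = list(consensus)
            truth.append((seq_id, offset))
        records.append((seq_id, "".join(seq)))
    return records, truth
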