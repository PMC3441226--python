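"""Readers and writers for the text formats the pipeline exchanges.

Formats
-------
* Expression matrix: TSV; first row ``probe_set`` followed by sample IDs;
  optional ``#tissue`` / ``#series`` metadata rows; then one row per probe set.
* Annotation catalog: TSV with columns ``probe_id <TAB> category <TAB>
  term1|term2|...``.
* Distance matrix: a relaxed Phylip dialect (full-length, whitespace-free
  names; classic Phylip truncates at 10 characters, which mangles Affymetrix
  IDs such as ``200725_x_at``).  ``strict_names=True`` truncates for
  interoperability with old tools.
* Trees: Newick with branch lengths, written with 9 significant digits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from os import PathLike
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np

from hgca.errors import ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from hgca.treecluster import CoexpressionTree, DistanceMatrix

#: Fixed vocabulary of annotation categories.
ANNOTATION_CATEGORIES = (
    "gene_name",
    "description",
    "go_bp",
    "go_cc",
    "go_mf",
    "ec",
    "omim",
    "pathway",
    "interpro",
    "transfac",
)

_TISSUE_ROW = "#tissue"
_SERIES_ROW = "#series"


class ProbeSetId(str):
    """A validated probe set identifier (e.g. ``"200725_x_at"``).

    Non-empty and whitespace-free.  IDs with the (case-sensitive) ``AFFX``
    prefix are hybridization/spike-in controls and are excluded from analysis.
    """

    __slots__ = ()

    def __new__(cls, value: str) -> "ProbeSetId":
        if not isinstance(value, str) or not value:
            raise ValidationError("probe set ID must be a non-empty string")
        if any(ch.isspace() for ch in value):
            raise ValidationError(f"probe set ID contains whitespace: {value!r}")
        return super().__new__(cls, value)

    @property
    def is_control(self) -> bool:
        return self.startswith("AFFX")


@dataclass
class ExpressionMatrix:
    """Probe-set x sample signal matrix with per-sample tissue/series labels.

    ``values[i, j]`` is the signal of ``probe_ids[i]`` in ``sample_ids[j]``;
    all values are finite and non-negative.
    """

    probe_ids: list[ProbeSetId]
    sample_ids: list[str]
    values: np.ndarray
    sample_meta: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probe_ids = [ProbeSetId(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value array shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe set IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.values.size and np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        meta = {}
        for sid in self.sample_ids:
            entry = dict(self.sample_meta.get(sid, {}))
            entry.setdefault("tissue", "")
            entry.setdefault("series", "")
            meta[sid] = entry
        self.sample_meta = meta

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe: str) -> int:
        try:
            return self.probe_ids.index(ProbeSetId(probe))
        except ValueError:
            from hgca.errors import ProbeLookupError

            raise ProbeLookupError(probe) from None

    def row(self, probe: str) -> np.ndarray:
        return self.values[self.probe_index(probe)]


@dataclass
class AnnotationCatalog:
    """Flat per-probe-set annotations grouped into a fixed category vocabulary.

    Probe sets absent from :attr:`entries` have empty term sets in every
    category.
    """

    entries: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, dict[str, set[str]]] = {}
        for probe, by_cat in self.entries.items():
            pid = ProbeSetId(probe)
            cleaned[pid] = {}
            for category, terms in by_cat.items():
                if category not in ANNOTATION_CATEGORIES:
                    raise ValidationError(f"unknown annotation category: {category!r}")
                cleaned[pid][category] = set(terms)
        self.entries = cleaned

    @property
    def probe_ids(self) -> list[ProbeSetId]:
        return list(self.entries)

    def terms(self, probe: str, category: str) -> frozenset[str]:
        if category not in ANNOTATION_CATEGORIES:
            raise ValidationError(f"unknown annotation category: {category!r}")
        return frozenset(self.entries.get(probe, {}).get(category, ()))

    def add(self, probe: str, category: str, *terms: str) -> None:
        if category not in ANNOTATION_CATEGORIES:
            raise ValidationError(f"unknown annotation category: {category!r}")
        self.entries.setdefault(ProbeSetId(probe), {}).setdefault(category, set()).update(terms)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | PathLike) -> ExpressionMatrix:
    """Parse a TSV expression matrix.

    The first row carries sample IDs; optional ``#tissue`` and ``#series``
    rows carry per-sample metadata; every other row is a probe set ID
    followed by one decimal value per sample (scientific notation accepted).
    Ragged rows, non-numeric cells and duplicate IDs raise :class:`ParseError`
    naming the offending row or column.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty expression matrix file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ParseError(f"{path}: header row has no sample IDs")
    if len(set(sample_ids)) != len(sample_ids):
        dup = _first_duplicate(sample_ids)
        raise ParseError(f"{path}: duplicate sample ID {dup!r} in header")
    n = len(sample_ids)

    meta = {sid: {"tissue": "", "series": ""} for sid in sample_ids}
    body_start = 1
    for key, row_no in ((_TISSUE_ROW, 1), (_SERIES_ROW, 2)):
        if body_start < len(lines) and lines[body_start].split("\t", 1)[0] == key:
            fields = lines[body_start].split("\t")[1:]
            if len(fields) != n:
                raise ParseError(
                    f"{path}: metadata row {key!r} has {len(fields)} fields, expected {n}"
                )
            label = key.lstrip("#")
            for sid, value in zip(sample_ids, fields):
                meta[sid][label] = value
            body_start += 1

    probe_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        fields = line.split("\t")
        probe = fields[0]
        if probe in seen:
            raise ParseError(f"{path}:{lineno}: duplicate probe set ID {probe!r}")
        seen.add(probe)
        if len(fields) - 1 != n:
            raise ParseError(
                f"{path}:{lineno}: probe {probe!r} has {len(fields) - 1} values, expected {n}"
            )
        row = []
        for col, cell in enumerate(fields[1:], start=2):
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column {col}"
                ) from None
        probe_ids.append(probe)
        rows.append(row)
    if not probe_ids:
        raise ParseError(f"{path}: no probe set rows")
    values = np.asarray(rows, dtype=float)
    return ExpressionMatrix(probe_ids, list(sample_ids), values, meta)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | PathLike) -> None:
    """Serialize *matrix* in the TSV schema understood by
    :func:`read_expression_matrix`.  Metadata rows are emitted only when some
    sample carries a non-empty tissue or series label."""
    meta = matrix.sample_meta
    tissues = [meta[s]["tissue"] for s in matrix.sample_ids]
    series = [meta[s]["series"] for s in matrix.sample_ids]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("probe_set\t" + "\t".join(matrix.sample_ids) + "\n")
        if any(tissues) or any(series):
            fh.write(_TISSUE_ROW + "\t" + "\t".join(tissues) + "\n")
            fh.write(_SERIES_ROW + "\t" + "\t".join(series) + "\n")
        for probe, row in zip(matrix.probe_ids, matrix.values):
            fh.write(probe + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    raise ValueError("no duplicate present")


# ---------------------------------------------------------------------------
# Annotation catalogs
# ---------------------------------------------------------------------------

def read_annotation_catalog(path: str | PathLike) -> AnnotationCatalog:
    """Parse a ``probe<TAB>category<TAB>term1|term2|...`` catalog file.

    A row with an empty term list registers the probe set as annotated (part
    of the enrichment universe) without assigning terms.
    """
    catalog = AnnotationCatalog()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2-3 tab-separated fields")
            probe, category = fields[0], fields[1]
            terms = [t for t in fields[2].split("|") if t] if len(fields) == 3 else []
            try:
                catalog.add(probe, category, *terms)
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return catalog


def write_annotation_catalog(catalog: AnnotationCatalog, path: str | PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for probe in sorted(catalog.entries):
            by_cat = catalog.entries[probe]
            if not by_cat:
                fh.write(f"{probe}\tdescription\n")
            for category in sorted(by_cat):
                terms = "|".join(sorted(by_cat[category]))
                fh.write(f"{probe}\t{category}\t{terms}\n")


# ---------------------------------------------------------------------------
# Phylip distance matrices (relaxed dialect)
# ---------------------------------------------------------------------------

def write_phylip_distances(
    distances: "DistanceMatrix", path: str | PathLike, strict_names: bool = False
) -> None:
    """Write a square distance matrix as Phylip text.

    Line 1 is the leaf count; each following line is a name and its full row
    of distances at full precision.  Names must be whitespace-free; with
    ``strict_names=True`` they are additionally truncated to 10 characters as
    classic Phylip requires.
    """
    d = np.asarray(distances.D, dtype=float)
    names = [str(p) for p in distances.probe_ids]
    if d.shape != (len(names), len(names)):
        raise ValidationError("distance matrix shape does not match leaf names")
    if not np.allclose(d, d.T, atol=1e-12, rtol=0.0):
        raise ValidationError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValidationError("distance matrix diagonal is not zero")
    for name in names:
        if any(ch.isspace() for ch in name):
            raise ValidationError(f"leaf name contains whitespace: {name!r}")
    if strict_names:
        names = [n[:10] for n in names]
        if len(set(names)) != len(names):
            raise ValidationError("strict 10-character truncation makes names collide")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{len(names)}\n")
        for name, row in zip(names, d):
            fh.write(name + " " + " ".join(repr(float(v)) for v in row) + "\n")


def read_phylip_distances(path: str | PathLike) -> "DistanceMatrix":
    """Read a (relaxed) Phylip distance matrix written by
    :func:`write_phylip_distances`."""
    from hgca.treecluster import DistanceMatrix

    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty Phylip file")
    try:
        count = int(lines[0].split()[0])
    except ValueError:
        raise ParseError(f"{path}:1: leaf count expected, got {lines[0]!r}") from None
    if len(lines) - 1 != count:
        raise ParseError(f"{path}: declared {count} leaves but found {len(lines) - 1} rows")
    names: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split()
        if len(fields) != count + 1:
            raise ParseError(
                f"{path}:{lineno}: expected name plus {count} distances, got {len(fields) - 1}"
            )
        names.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric distance") from None
    return DistanceMatrix(names, np.asarray(rows, dtype=float))


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def dumps_newick(tree: "CoexpressionTree") -> str:
    """Render *tree* as a Newick string with 9-significant-digit branch
    lengths and a terminating semicolon.  Internal nodes are unlabeled."""

    def render(node) -> str:
        if node.is_leaf:
            label = node.name
        else:
            label = "(" + ",".join(render(c) for c in node.children) + ")"
        if node.length is None:
            return label
        return f"{label}:{_format_length(node.length)}"

    return render(tree.root) + ";"


def _format_length(value: float) -> str:
    if value == 0:
        return "0"
    text = f"{value:.9g}"
    return text


def write_newick(tree: "CoexpressionTree", path: str | PathLike) -> None:
    names = [leaf.name for leaf in tree.root.leaves()]
    if len(set(names)) != len(names):
        raise ValidationError("tree leaf names are not unique")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(dumps_newick(tree) + "\n")


def loads_newick(text: str) -> "CoexpressionTree":
    """Parse a Newick string into a tree.

    Unquoted labels only; unlabeled internal nodes allowed; malformed input
    raises :class:`ParseError` with the 0-based character offset.
    """
    from hgca.treecluster import CoexpressionTree, TreeNode

    s = text.strip()
    if not s:
        raise ParseError("offset 0: empty Newick string")
    pos = 0

    def fail(msg: str) -> "ParseError":
        return ParseError(f"offset {pos}: {msg}")

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children = [parse_node()]
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise fail("expected ')' or ','")
            pos += 1
            node.children = children
            for child in children:
                child.parent = node
        label = _scan_label()
        if label:
            node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            node.length = _scan_number()
        return node

    def _scan_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def _scan_number() -> float:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        token = s[start:pos].strip()
        try:
            value = float(token)
        except ValueError:
            raise ParseError(f"offset {start}: invalid branch length {token!r}") from None
        if not math.isfinite(value):
            raise ParseError(f"offset {start}: non-finite branch length")
        return value

    root = parse_node()
    if pos >= len(s) or s[pos] != ";":
        raise fail("expected terminating ';'")
    pos += 1
    if s[pos:].strip():
        raise fail("trailing characters after ';'")
    names = [leaf.name for leaf in root.leaves()]
    if any(n is None or n == "" for n in names):
        raise ParseError("offset 0: unlabeled leaf")
    if len(set(names)) != len(names):
        raise ParseError("offset 0: duplicate leaf names")
    return CoexpressionTree(root)


def read_newick(path: str | PathLike) -> "CoexpressionTree":
    with open(path, "rt", encoding="utf-8") as fh:
        return loads_newick(fh.read())
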