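"""Promoter scanning with position weight matrices.

Scoring follows the information-weighted, min-max-normalized similarity
scheme of matrix-based binding-site search tools: position *i* with observed
base *b* contributes ``info(i) * freq(i, b)``, where ``info(i) =
sum_b freq(i, b) * ln(4 freq(i, b))`` (0 at a uniform position, ln 4 at a
degenerate one).  The raw sum S is normalized to ``(S - Min) / (Max - Min)``
with Max/Min built from the per-position best/worst bases.  The *core* is
the 5 consecutive positions with the highest total information; core
similarity (CSS) acts as a pre-filter before the full matrix similarity
(MSS).  Default stringency: CSS >= 0.95, MSS >= 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

import numpy as np

from hgca.errors import ParseError, ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CORE_LENGTH = 5

DEFAULT_CORE_CUTOFF = 0.95
DEFAULT_MATRIX_CUTOFF = 0.90
PROMOTER_LENGTH = 500

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def information_vector(freq: np.ndarray) -> np.ndarray:
    """Per-position information weights of a frequency matrix.

    ``info(i) = sum_b freq(i, b) * ln(4 * freq(i, b))`` with ``0 ln 0 = 0``;
    each row must sum to 1.
    """
    freq = np.asarray(freq, dtype=float)
    if freq.ndim != 2 or freq.shape[1] != 4:
        raise ValidationError("frequency matrix must be L x 4")
    if np.any(freq < 0):
        raise ValidationError("frequencies must be non-negative")
    sums = freq.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValidationError(f"frequency row {bad} sums to {sums[bad]!r}, not 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, freq * np.log(4.0 * freq), 0.0)
    return terms.sum(axis=1)


def find_core(info: np.ndarray, core_length: int = CORE_LENGTH) -> int:
    """Start index of the *core_length* consecutive positions maximizing the
    summed information; ties resolve to the smallest start."""
    info = np.asarray(info, dtype=float)
    if info.size < core_length:
        raise ValidationError(f"matrix shorter than the {core_length}-position core")
    windows = np.convolve(info, np.ones(core_length), mode="valid")
    return int(np.argmax(windows))


@dataclass
class Pwm:
    """Position frequency matrix with information weights and core window."""

    name: str
    freq: np.ndarray
    info: np.ndarray = field(init=False)
    core_start: int = field(init=False)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.info = information_vector(self.freq)
        self.core_start = find_core(self.info)

    @classmethod
    def from_counts(
        cls, name: str, counts: Sequence[Sequence[float]], pseudocount: float = 0.0
    ) -> "Pwm":
        """Build from a count matrix; rows are normalized to frequencies
        after adding *pseudocount* to every cell."""
        arr = np.asarray(counts, dtype=float) + pseudocount
        sums = arr.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValidationError(f"{name}: count row sums must be positive")
        return cls(name, arr / sums)

    def __len__(self) -> int:
        return self.freq.shape[0]

    @property
    def core_positions(self) -> range:
        return range(self.core_start, self.core_start + CORE_LENGTH)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.freq, axis=1))


@dataclass(frozen=True)
class PwmHit:
    """A reported binding-site match, in plus-strand coordinates."""

    sequence_id: str
    offset: int
    strand: str
    pwm_name: str
    css: float
    mss: float
    site: str


def similarity(window: str, pwm: Pwm, positions: Iterable[int] | None = None) -> float:
    """Min-max-normalized information-weighted similarity of *window* to
    *pwm* over *positions* (default: every position)."""
    if len(window) != len(pwm):
        raise ValidationError(f"window length {len(window)} != matrix length {len(pwm)}")
    pos = list(range(len(pwm))) if positions is None else sorted(positions)
    try:
        codes = [_BASE_INDEX[window[i].upper()] for i in pos]
    except KeyError as exc:
        raise ValidationError(f"non-ACGT base in window: {exc.args[0]!r}") from None
    info = pwm.info[pos]
    freq = pwm.freq[pos]
    score = float(np.sum(info * freq[np.arange(len(pos)), codes]))
    max_score = float(np.sum(info * freq.max(axis=1)))
    min_score = float(np.sum(info * freq.min(axis=1)))
    if max_score == min_score:
        raise ValidationError(
            f"{pwm.name}: uniform matrix over the scored positions; similarity undefined"
        )
    return (score - min_score) / (max_score - min_score)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _scan_strand(
    seq: str,
    seq_len: int,
    sequence_id: str,
    strand: str,
    pwm: Pwm,
    core_cutoff: float,
    matrix_cutoff: float,
) -> list[PwmHit]:
    length = len(pwm)
    n_windows = len(seq) - length + 1
    if n_windows <= 0:
        return []
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code_map = np.full(128, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        code_map[ord(base)] = idx
    coded = code_map[codes]

    window_idx = np.arange(n_windows)[:, None] + np.arange(length)[None, :]
    W = coded[window_idx]  # n_windows x L base codes, -1 for N
    valid = np.all(W >= 0, axis=1)

    pos = np.arange(length)
    contrib = np.where(
        W >= 0, pwm.info[None, :] * pwm.freq[pos[None, :], np.where(W >= 0, W, 0)], 0.0
    )
    core = np.asarray(pwm.core_positions)
    info_max = pwm.info * pwm.freq.max(axis=1)
    info_min = pwm.info * pwm.freq.min(axis=1)

    def normalize(raw: np.ndarray, idx: np.ndarray) -> np.ndarray:
        hi = float(info_max[idx].sum())
        lo = float(info_min[idx].sum())
        if hi == lo:
            raise ValidationError(
                f"{pwm.name}: uniform matrix over the scored positions; similarity undefined"
            )
        return (raw - lo) / (hi - lo)

    css = normalize(contrib[:, core].sum(axis=1), core)
    mss = normalize(contrib.sum(axis=1), pos)

    hits = []
    passing = np.nonzero(valid & (css >= core_cutoff) & (mss >= matrix_cutoff))[0]
    for j in passing:
        j = int(j)
        offset = j if strand == "+" else seq_len - length - j
        hits.append(
            PwmHit(
                sequence_id=sequence_id,
                offset=offset,
                strand=strand,
                pwm_name=pwm.name,
                css=float(css[j]),
                mss=float(mss[j]),
                site=seq[j : j + length],
            )
        )
    return hits


def scan(
    sequences: Iterable[tuple[str, str]],
    pwms: Sequence[Pwm],
    core_cutoff: float = DEFAULT_CORE_CUTOFF,
    matrix_cutoff: float = DEFAULT_MATRIX_CUTOFF,
    both_strands: bool = True,
) -> list[PwmHit]:
    """Scan ``(sequence_id, sequence)`` pairs with every matrix.

    Windows containing N are skipped.  A window is reported when its core
    similarity passes *core_cutoff* and then its matrix similarity passes
    *matrix_cutoff*.  Minus-strand windows are scored on the reverse
    complement and reported at the mirrored plus-strand offset.  Hits are
    sorted by sequence, offset, strand, matrix name.
    """
    hits: list[PwmHit] = []
    for sequence_id, raw_seq in sequences:
        seq = raw_seq.upper()
        if any(ch not in "ACGTN" for ch in seq):
            bad = next(ch for ch in seq if ch not in "ACGTN")
            raise ValidationError(f"{sequence_id}: unexpected base {bad!r}")
        for pwm in pwms:
            hits.extend(
                _scan_strand(seq, len(seq), sequence_id, "+", pwm, core_cutoff, matrix_cutoff)
            )
            if both_strands:
                hits.extend(
                    _scan_strand(
                        reverse_complement(seq), len(seq), sequence_id, "-", pwm,
                        core_cutoff, matrix_cutoff,
                    )
                )
    hits.sort(key=lambda h: (h.sequence_id, h.offset, h.strand, h.pwm_name))
    return hits


def promoter_window(tss: int, strand: str, upstream: int = PROMOTER_LENGTH) -> tuple[int, int]:
    """0-based half-open reference interval of the *upstream* bp promoter.

    *tss* is 1-based.  Plus strand: ``[max(0, tss-1-upstream), tss-1)``;
    minus strand: ``[tss, tss+upstream)`` (to be scanned as the reverse
    complement).
    """
    if tss < 1:
        raise ValidationError("tss must be >= 1 (1-based)")
    if strand == "+":
        end = tss - 1
        return (max(0, end - upstream), end)
    if strand == "-":
        return (tss, tss + upstream)
    raise ValidationError(f"strand must be '+' or '-', got {strand!r}")


# ---------------------------------------------------------------------------
# PWM file format: blocks of ">name" followed by L rows of 4 numbers (A C G T)
# ---------------------------------------------------------------------------

def read_pwms(path: str | PathLike, pseudocount: float = 0.0) -> list[Pwm]:
    """Read count/frequency matrices from the simple block text format."""
    pwms: list[Pwm] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal name, rows
        if name is None:
            return
        if not rows:
            raise ParseError(f"{path}:{lineno}: matrix {name!r} has no rows")
        pwms.append(Pwm.from_counts(name, rows, pseudocount=pseudocount))
        name, rows = None, []

    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush(lineno)
                name = line[1:].strip()
                if not name:
                    raise ParseError(f"{path}:{lineno}: empty matrix name")
                continue
            if name is None:
                raise ParseError(f"{path}:{lineno}: matrix row before any '>' header")
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 values (A C G T)")
            try:
                rows.append([float(v) for v in fields])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric matrix value") from None
    flush(lineno=-1)
    if not pwms:
        raise ParseError(f"{path}: no matrices found")
    return pwms


def write_pwms(pwms: Sequence[Pwm], path: str | PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.freq:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def write_hits(hits: Sequence[PwmHit], path: str | PathLike) -> None:
    """BED-like TSV: sequence, start, end, matrix name, MSS, strand, CSS.

    Coordinates are 0-based half-open as in BED.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#sequence\tstart\tend\tpwm\tmss\tstrand\tcss\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.offset}\t{h.offset + len(h.site)}\t"
                f"{h.pwm_name}\t{h.mss:.6g}\t{h.strand}\t{h.css:.6g}\n"
            )
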