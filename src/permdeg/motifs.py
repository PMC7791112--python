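"""JASPAR-style PFM parsing, log-odds PWM construction and relative-score
sequence scanning.

The relative score of a window is its log-odds score min-max normalized over
the matrix's own attainable range, ``(S - S_min) / (S_max - S_min)``; it is 1
exactly on a per-column argmax (consensus) path and 0 on the anti-consensus.
Binding-site predictions keep windows with relative score strictly above the
threshold (default 0.9).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionFrequencyMatrix:
    """Base counts per motif column; rows ordered A, C, G, T."""

    motif_id: str
    name: str
    counts: np.ndarray  # (4, L)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise FormatError("PFM counts must be a 4 x L array")
        if self.counts.shape[1] < 1:
            raise FormatError("PFM must have at least one column")
        if (self.counts < 0).any():
            raise FormatError("PFM counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise FormatError("every PFM column must have a positive sum")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        """Per-column argmax base; ties resolved in A,C,G,T order."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass
class PositionWeightMatrix:
    """Log2-odds weights with the per-matrix score bounds used for the
    relative score."""

    motif_id: str
    log_odds: np.ndarray  # (4, L)
    pseudocount: float
    background: np.ndarray  # (4,)
    s_min: float = field(init=False)
    s_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.s_min = float(self.log_odds.min(axis=0).sum())
        self.s_max = float(self.log_odds.max(axis=0).sum())
        if not self.s_max > self.s_min:
            raise ParameterError(
                f"motif {self.motif_id!r} is uninformative (s_max == s_min)"
            )

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    def relative(self, raw_score: float) -> float:
        return (raw_score - self.s_min) / (self.s_max - self.s_min)


@dataclass(frozen=True)
class MotifHit:
    """One PWM match in plus-strand, 0-based half-open coordinates."""

    sequence_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    raw_score: float
    relative_score: float


_HEADER_RE = re.compile(r"^>\s*(\S+)\s*(.*)$")


def _parse_count_row(line: str, lineno: int) -> tuple[str | None, list[float]]:
    """One PFM row, either ``A [ 3 5 0 ]`` (JASPAR) or ``A 3 5 0`` or a bare
    ``3 5 0`` (rows then taken in A,C,G,T order)."""
    stripped = line.strip()
    base: str | None = None
    body = stripped
    if stripped[:1].upper() in _BASE_INDEX and (
        len(stripped) == 1 or not stripped[1].isalnum()
    ):
        base = stripped[0].upper()
        body = stripped[1:]
    body = body.replace("[", " ").replace("]", " ")
    try:
        values = [float(tok) for tok in body.split()]
    except ValueError as exc:
        raise FormatError(f"unparseable count in PFM row: {exc}", lineno)
    if not values:
        raise FormatError("empty PFM count row", lineno)
    return base, values


def parse_jaspar_all(text: str) -> list[PositionFrequencyMatrix]:
    """Parse every motif in a JASPAR flat file (both the bracketed and the
    plain whitespace dialects)."""
    motifs: list[PositionFrequencyMatrix] = []
    header: tuple[str, str, int] | None = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []

    def flush() -> None:
        nonlocal header, rows, order
        if header is None:
            return
        motif_id, name, lineno = header
        if len(rows) != 4:
            raise FormatError(
                f"motif {motif_id!r} has {len(rows)} base rows; need 4", lineno
            )
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise FormatError(
                f"motif {motif_id!r} has ragged rows (lengths "
                f"{sorted(len(rows[b]) for b in BASES)})",
                lineno,
            )
        counts = np.array([rows[b] for b in BASES], dtype=float)
        motifs.append(PositionFrequencyMatrix(motif_id, name, counts))
        header, rows, order = None, {}, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _HEADER_RE.match(line)
        if m:
            flush()
            motif_id = m.group(1)
            name = m.group(2).strip() or motif_id
            header = (motif_id, name, lineno)
            continue
        if header is None:
            raise FormatError("PFM counts before any '>' header", lineno)
        base, values = _parse_count_row(line, lineno)
        if base is None:
            remaining = [b for b in BASES if b not in rows]
            if not remaining:
                raise FormatError("more than 4 PFM rows", lineno)
            base = remaining[0]
        if base in rows:
            raise FormatError(f"duplicate PFM row for base {base}", lineno)
        rows[base] = values
        order.append(base)
    flush()
    if not motifs:
        raise FormatError("no motif found in PFM text")
    return motifs


def parse_jaspar(text: str) -> PositionFrequencyMatrix:
    """Parse a single JASPAR motif (the first, if several are present)."""
    return parse_jaspar_all(text)[0]


def format_jaspar(pfm: PositionFrequencyMatrix) -> str:
    lines = [f">{pfm.motif_id} {pfm.name}"]
    for i, b in enumerate(BASES):
        row = " ".join(f"{v:g}" for v in pfm.counts[i])
        lines.append(f"{b} [ {row} ]")
    return "\n".join(lines) + "\n"


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    pseudocount: float = 0.8,
    background: Sequence[float] | None = None,
) -> PositionWeightMatrix:
    """Convert counts to log2-odds weights.

    Per column ``j``: ``p(b, j) = (count + pseudocount * bg_b) /
    (colsum + pseudocount)``; the weight is ``log2(p / bg_b)``. The
    pseudocount is distributed over bases in proportion to the background,
    so the column probabilities sum to one.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if bg.shape != (4,) or (bg <= 0).any():
        raise ParameterError("background must be 4 positive probabilities")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ParameterError("background probabilities must sum to 1")
    if pseudocount == 0 and (pfm.counts == 0).any():
        raise ParameterError(
            "zero counts require a positive pseudocount for log-odds"
        )
    colsum = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    log_odds = np.log2(probs / bg[:, None])
    return PositionWeightMatrix(pfm.motif_id, log_odds, pseudocount, bg)


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    codes = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ParameterError(f"sequence contains invalid characters {sorted(bad)}")
    return codes


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Score every length-L window; windows containing N (code -1) get NaN."""
    L = weights.shape[1]
    n_windows = len(codes) - L + 1
    if n_windows <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win >= 0).all(axis=1)
    scores = np.full(n_windows, np.nan)
    if valid.any():
        idx = win[valid].astype(np.intp)
        scores[valid] = weights[idx, np.arange(L)].sum(axis=1)
    return scores


def scan_sequence(
    sequence: str,
    pwm: PositionWeightMatrix,
    threshold: float = 0.9,
    both_strands: bool = True,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """All windows with relative score strictly above ``threshold``.

    Minus-strand windows are scored on the reverse complement but reported
    in plus-strand coordinates. Windows containing N are skipped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError("threshold must be in [0, 1]")
    codes = _encode(sequence)
    span = pwm.s_max - pwm.s_min
    hits: list[MotifHit] = []
    # Scoring a window on the minus strand equals scoring the plus-strand
    # window with the base-complemented, position-reversed weight matrix.
    strands = [("+", pwm.log_odds)]
    if both_strands:
        strands.append(("-", pwm.log_odds[::-1, ::-1]))
    for strand, weights in strands:
        scores = _window_scores(codes, weights)
        for start in np.flatnonzero(~np.isnan(scores)):
            raw = float(scores[start])
            rel = (raw - pwm.s_min) / span
            if rel > threshold:
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id,
                        start=int(start),
                        end=int(start) + pwm.length,
                        strand=strand,
                        raw_score=raw,
                        relative_score=rel,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def rank_predicted_tfs(
    hits_by_motif: Mapping[str, Iterable[MotifHit]],
) -> pd.DataFrame:
    """One row per motif with at least one hit, ordered by best relative
    score descending; ties broken by motif id."""
    rows = []
    for motif_id, hits in hits_by_motif.items():
        hits = list(hits)
        if not hits:
            continue
        best = max(h.relative_score for h in hits)
        rows.append(
            {"motif_id": motif_id, "best_relative_score": best, "n_hits": len(hits)}
        )
    frame = pd.DataFrame(rows, columns=["motif_id", "best_relative_score", "n_hits"])
    if len(frame):
        frame = frame.sort_values(
            ["best_relative_score", "motif_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame
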