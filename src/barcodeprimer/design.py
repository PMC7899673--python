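"""Degenerate consensus primer design from a multiple sequence alignment.

The design rule is the classic one for degenerate primers: slide a window
over the alignment, take per-column IUPAC union consensus (the smallest
ambiguity code covering every observed base), and keep windows whose total
degeneracy stays below a cap.  Windows with low degeneracy are conserved
regions — candidate primer sites.  Forward and reverse candidates are then
paired under an amplicon-length constraint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .iupac import (
    IUPAC_CODES,
    base_set,
    code_for_set,
    degeneracy,
    match_base,
    reverse_complement,
)
from .seqio import AlignmentBlock

__all__ = [
    "DesignParams",
    "CandidatePrimer",
    "PrimerPairCandidate",
    "column_consensus",
    "scan_windows",
    "pair_primers",
]


@dataclass(frozen=True)
class DesignParams:
    """Tunable constraints for the window scan.

    ``primer_length_range``          candidate lengths in bases, inclusive.
    ``max_degeneracy``               cap on the consensus expansion-pool size.
    ``max_gap_fraction_per_column``  columns gappier than this are ineligible
                                     (0.0 = any gap disqualifies the column).
    ``amplicon_length_range``        acceptable product length in alignment
                                     columns, 5' end of the forward window to
                                     3' end of the reverse window.
    ``search_regions``               optional 1-based [start, end] column
                                     intervals restricting the scan.
    ``min_base_frequency``           frequency floor below which an observed
                                     base is dropped from the column consensus
                                     (0.0 keeps every observed base).
    """

    primer_length_range: tuple[int, int] = (20, 26)
    max_degeneracy: int = 32
    max_gap_fraction_per_column: float = 0.0
    amplicon_length_range: tuple[int, int] = (400, 1000)
    search_regions: tuple[tuple[int, int], ...] | None = None
    min_base_frequency: float = 0.0

    def __post_init__(self):
        lo, hi = self.primer_length_range
        alo, ahi = self.amplicon_length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad primer length range {self.primer_length_range}")
        if not (1 <= alo <= ahi):
            raise ValueError(f"bad amplicon length range {self.amplicon_length_range}")
        if self.max_degeneracy < 1:
            raise ValueError("max_degeneracy must be >= 1")
        if not 0.0 <= self.min_base_frequency <= 1.0:
            raise ValueError("min_base_frequency must lie in [0, 1]")


@dataclass(frozen=True)
class CandidatePrimer:
    """One scored window: 1-based column interval plus its consensus.

    ``consensus`` is written 5'->3' in primer orientation, i.e. reverse
    candidates carry the reverse complement of the window consensus.
    ``coverage`` is the fraction of alignment rows the consensus matches
    with zero mismatches.
    """

    window: tuple[int, int]
    consensus: str
    degeneracy: int
    coverage: float
    orientation: str

    @property
    def start(self) -> int:
        return self.window[0]

    @property
    def end(self) -> int:
        return self.window[1]

    def __len__(self) -> int:
        return self.window[1] - self.window[0] + 1


class PrimerPairCandidate(NamedTuple):
    forward: CandidatePrimer
    reverse: CandidatePrimer
    predicted_amplicon_length: int


def column_consensus(column: Sequence[str], min_base_frequency: float = 0.0) -> str:
    """IUPAC code for the union of bases observed in one alignment column.

    A degenerate entry contributes its whole base set.  A base is kept when
    its frequency among non-gap entries is >= ``min_base_frequency``; if the
    floor excludes everything, the most frequent base(s) are kept so the
    consensus never becomes empty.  All-gap columns are rejected.
    """
    if not column:
        raise ValueError("empty column")
    counts: Counter[str] = Counter()
    n_nongap = 0
    for entry in column:
        if entry == "-":
            continue
        n_nongap += 1
        for b in base_set(entry):
            counts[b] += 1
    if n_nongap == 0:
        raise ValueError("all-gap column has no consensus")
    kept = {b for b, c in counts.items() if c / n_nongap >= min_base_frequency}
    if not kept:
        top = max(counts.values())
        kept = {b for b, c in counts.items() if c == top}
    return code_for_set(kept)


def _column_profiles(
    block: AlignmentBlock, params: DesignParams
) -> tuple[list[str | None], np.ndarray]:
    """Per-column consensus (None where gap-ineligible) and row-match matrix."""
    n_rows, n_cols = block.n_rows, block.length
    consensus: list[str | None] = []
    for col in range(1, n_cols + 1):
        column = block.column(col)
        gap_frac = column.count("-") / n_rows
        if gap_frac > params.max_gap_fraction_per_column or gap_frac == 1.0:
            consensus.append(None)
            continue
        consensus.append(column_consensus(column, params.min_base_frequency))
    matches = np.zeros((n_rows, n_cols), dtype=bool)
    for j, code in enumerate(consensus):
        if code is None:
            continue
        for i, rec in enumerate(block.records):
            ch = rec.sequence[j]
            matches[i, j] = ch != "-" and match_base(ch, code)
    return consensus, matches


def _allowed_starts(n_cols: int, length: int, params: DesignParams) -> list[int]:
    if params.search_regions is None:
        return list(range(1, n_cols - length + 2))
    starts: list[int] = []
    for lo, hi in params.search_regions:
        lo, hi = max(1, lo), min(n_cols, hi)
        starts.extend(range(lo, hi - length + 2))
    return sorted(set(starts))


def scan_windows(
    block: AlignmentBlock,
    params: DesignParams | None = None,
    *,
    with_diagnostics: bool = False,
):
    """Enumerate every window whose consensus degeneracy is within the cap.

    Each eligible window yields one forward candidate (the window consensus)
    and one reverse candidate (its reverse complement).  Candidates are
    sorted by (degeneracy ascending, coverage descending, start ascending,
    length ascending).  With ``with_diagnostics`` a Counter of rejection
    reasons is returned alongside, which the CLI surfaces when the scan
    comes back empty.
    """
    params = params or DesignParams()
    min_len, max_len = params.primer_length_range
    if block.length < max_len:
        raise ValueError(
            f"alignment has {block.length} columns, fewer than the maximum "
            f"primer length {max_len}"
        )
    consensus, matches = _column_profiles(block, params)
    sizes = np.array(
        [len(IUPAC_CODES[c]) if c is not None else 0 for c in consensus], dtype=np.int64
    )
    eligible = np.array([c is not None for c in consensus])
    rejections: Counter[str] = Counter()
    candidates: list[CandidatePrimer] = []
    n_rows = block.n_rows
    row_cum = np.cumsum(matches, axis=1)  # rows x cols, running match count
    for length in range(min_len, max_len + 1):
        for start in _allowed_starts(block.length, length, params):
            lo, hi = start - 1, start - 1 + length  # 0-based half-open
            if not eligible[lo:hi].all():
                rejections["gap_column"] += 1
                continue
            deg = int(np.prod(sizes[lo:hi]))
            if deg > params.max_degeneracy:
                rejections["degeneracy_exceeded"] += 1
                continue
            window_matches = row_cum[:, hi - 1] - (row_cum[:, lo - 1] if lo else 0)
            coverage = float(np.count_nonzero(window_matches == length)) / n_rows
            cons = "".join(consensus[lo:hi])  # type: ignore[arg-type]
            win = (start, start + length - 1)
            candidates.append(
                CandidatePrimer(win, cons, deg, coverage, "forward")
            )
            candidates.append(
                CandidatePrimer(win, reverse_complement(cons), deg, coverage, "reverse")
            )
    candidates.sort(key=lambda c: (c.degeneracy, -c.coverage, c.start, len(c)))
    if with_diagnostics:
        return candidates, rejections
    return candidates


def pair_primers(
    candidates: Sequence[CandidatePrimer],
    params: DesignParams | None = None,
) -> list[PrimerPairCandidate]:
    """All forward/reverse pairs with an in-range implied product length.

    Product length is measured in alignment columns from the forward
    window's 5' end to the reverse window's 3' end (reverse-window end -
    forward-window start + 1); windows must not overlap.  Pairs are ranked
    by combined (product) degeneracy ascending, then combined coverage
    descending, then leftmost forward and reverse starts.
    """
    params = params or DesignParams()
    alo, ahi = params.amplicon_length_range
    forwards = [c for c in candidates if c.orientation == "forward"]
    reverses = [c for c in candidates if c.orientation == "reverse"]
    pairs: list[PrimerPairCandidate] = []
    for f in forwards:
        for r in reverses:
            if f.end >= r.start:
                continue
            product = r.end - f.start + 1
            if alo <= product <= ahi:
                pairs.append(PrimerPairCandidate(f, r, product))
    pairs.sort(
        key=lambda p: (
            p.forward.degeneracy * p.reverse.degeneracy,
            -(p.forward.coverage * p.reverse.coverage),
            p.forward.start,
            p.reverse.start,
            len(p.forward),
            len(p.reverse),
        )
    )
    return pairs
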