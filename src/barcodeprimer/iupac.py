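"""Exact algebra over IUPAC nucleotide ambiguity codes.

Every operation here treats a degenerate base as the *set* of plain bases it
denotes (R = {A,G}, H = {A,C,T}, N = {A,C,G,T}, ...).  A degenerate primer is
then a compact notation for the Cartesian product of its per-position base
sets, and two bases "match" exactly when their sets intersect.  These pure
functions underpin primer design, binding-site search and the property
report; none of them touches I/O or global state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

__all__ = [
    "IUPAC_CODES",
    "InvalidSequenceError",
    "Primer",
    "base_set",
    "code_for_set",
    "complement_code",
    "degeneracy",
    "reported_degeneracy",
    "expand",
    "gc_percent",
    "match_base",
    "melting_temperature",
    "reverse_complement",
    "validate_sequence",
]

#: code -> the subset of {A, C, G, T} it denotes
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: frozenset of plain bases -> its unique IUPAC code (inverse of IUPAC_CODES)
_SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in IUPAC_CODES.items()}

_COMPLEMENT_PLAIN = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: code -> complementary code, derived set-wise (R<->Y, K<->M, B<->V, D<->H;
#: S, W and N are self-complementary)
_COMPLEMENT: dict[str, str] = {
    code: _SET_TO_CODE[frozenset(_COMPLEMENT_PLAIN[b] for b in s)]
    for code, s in IUPAC_CODES.items()
}


class InvalidSequenceError(ValueError):
    """Raised for characters outside the IUPAC alphabet (1-based position)."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


def validate_sequence(seq: str, *, allow_gaps: bool = False, context: str = "sequence") -> str:
    """Upper-case ``seq`` and reject anything outside the IUPAC alphabet.

    Gap characters ('-') are legal only when ``allow_gaps`` is set, i.e. in
    alignment columns — never inside a primer.  Uracil is always rejected.
    Returns the upper-cased sequence.
    """
    if not seq:
        raise InvalidSequenceError(f"empty {context}")
    up = seq.upper()
    for i, ch in enumerate(up, start=1):
        if ch in IUPAC_CODES:
            continue
        if ch == "-" and allow_gaps:
            continue
        raise InvalidSequenceError(
            f"invalid character {ch!r} at position {i} in {context}", position=i
        )
    return up


def base_set(code: str) -> frozenset[str]:
    """The subset of {A,C,G,T} denoted by one IUPAC code."""
    try:
        return IUPAC_CODES[code.upper()]
    except KeyError:
        raise InvalidSequenceError(f"invalid IUPAC code {code!r}") from None


def code_for_set(bases: Iterable[str]) -> str:
    """The unique IUPAC code whose base set equals ``bases``."""
    s = frozenset(b.upper() for b in bases)
    try:
        return _SET_TO_CODE[s]
    except KeyError:
        raise InvalidSequenceError(f"no IUPAC code for base set {sorted(s)}") from None


def complement_code(code: str) -> str:
    """Set-wise complement of one code (an involution)."""
    try:
        return _COMPLEMENT[code.upper()]
    except KeyError:
        raise InvalidSequenceError(f"invalid IUPAC code {code!r}") from None


def degeneracy(seq: str) -> int:
    """Number of distinct plain sequences a degenerate sequence denotes.

    The product over positions of the base-set size; 1 for a sequence with no
    ambiguity codes.
    """
    seq = validate_sequence(seq, context="primer sequence")
    d = 1
    for ch in seq:
        d *= len(IUPAC_CODES[ch])
    return d


def reported_degeneracy(seq: str) -> int:
    """Degeneracy using the primer-table convention: 0 when there is none.

    Primer tables conventionally print 0 (rather than 1) for a primer with no
    ambiguous position; a degenerate primer is printed with its fold
    degeneracy.  ``degeneracy`` keeps the mathematical product; use this for
    display.
    """
    d = degeneracy(seq)
    return d if d > 1 else 0


def expand(seq: str, cap: int = 4096) -> set[str]:
    """Enumerate the plain ACGT sequences a degenerate sequence denotes.

    Refuses (ValueError naming the cap) when the degeneracy exceeds ``cap`` so
    callers cannot accidentally materialise a combinatorial pool.
    """
    seq = validate_sequence(seq, context="primer sequence")
    d = degeneracy(seq)
    if d > cap:
        raise ValueError(
            f"degeneracy {d} of {seq!r} exceeds the expansion cap of {cap}"
        )
    pools = [sorted(IUPAC_CODES[ch]) for ch in seq]
    return {"".join(p) for p in itertools.product(*pools)}


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (an involution)."""
    seq = validate_sequence(seq, context="sequence")
    return "".join(_COMPLEMENT[ch] for ch in reversed(seq))


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gc_percent(seq: str) -> float:
    """GC content in percent, rounded half-up to one decimal.

    Counts only positions whose code is unambiguously G or C — the plain bases
    G and C plus the code S ({C,G}).  Partially-GC ambiguity codes (R, Y, K,
    M, ...) contribute nothing.  This fixed-base convention is the one primer
    tables use for degenerate primers.
    """
    seq = validate_sequence(seq, context="primer sequence")
    n_gc = sum(1 for ch in seq if ch in ("G", "C", "S"))
    return _round_half_up(100.0 * n_gc / len(seq), 1)


def melting_temperature(seq: str, method: str = "wallace") -> float:
    """Estimate the melting temperature in degrees Celsius.

    ``wallace``    -- the Wallace rule 2*(A+T) + 4*(G+C), the usual quick
                      estimate for primers up to ~25 nt.
    ``gc_formula`` -- the GC-fraction formula 64.9 + 41*(GC - 16.4)/length.

    Ambiguous positions contribute the average over their base set, so a
    degenerate primer's Tm is the mean over its expansion pool.  Neither
    method models salt or nearest-neighbour stacking.
    """
    seq = validate_sequence(seq, context="primer sequence")
    # expected number of G/C per position, averaged over the base set
    gc_exp = sum(
        len(IUPAC_CODES[ch] & frozenset("GC")) / len(IUPAC_CODES[ch]) for ch in seq
    )
    n = len(seq)
    if method == "wallace":
        at_exp = n - gc_exp
        return 2.0 * at_exp + 4.0 * gc_exp
    if method == "gc_formula":
        return 64.9 + 41.0 * (gc_exp - 16.4) / n
    raise ValueError(f"unknown melting-temperature method {method!r}")


def match_base(template: str, primer: str) -> bool:
    """True iff the two codes' base sets intersect.

    This is the matching rule for degenerate hybridisation: a template 'A'
    pairs with a primer 'H' (= A/C/T) because the primer pool contains an 'A'
    variant, while 'G' vs 'H' cannot pair.  A template 'N' matches anything.
    """
    return bool(base_set(template) & base_set(primer))


@dataclass(frozen=True)
class Primer:
    """A named degenerate oligonucleotide with its orientation.

    ``sequence`` is stored 5'->3' as written in a primer table; ``orientation``
    is ``"forward"`` or ``"reverse"``.  A reverse primer anneals to the plus
    strand as its reverse complement.
    """

    name: str
    sequence: str
    orientation: str

    def __post_init__(self):
        object.__setattr__(
            self, "sequence", validate_sequence(self.sequence, context=f"primer {self.name!r}")
        )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(
                f"orientation must be 'forward' or 'reverse', got {self.orientation!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence)

    @property
    def gc_percent(self) -> float:
        return gc_percent(self.sequence)

    def tm(self, method: str = "wallace") -> float:
        return melting_temperature(self.sequence, method)
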