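"""Synthetic COI-like panels with planted primer sites, plus packaged primers.

The generator emulates the situation degenerate barcoding primers are
designed for: a panel of homologous sequences that are conserved in two
windows (the primer sites) flanking a variable core.  It draws one random
ancestor, copies it, mutates the core at a per-site substitution rate, and
inside the planted windows applies only an explicit per-column polymorphism
spec — so the ground-truth degenerate consensus of each window is known
exactly and design/validation can be scored against it.

Indels are not simulated: primer-site conservation, not alignment, is the
phenomenon under test, so the generated panel is both the "alignment" and a
gap-free reference set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .insilico import PrimerPair
from .iupac import Primer, code_for_set, reverse_complement
from .seqio import AlignmentBlock, SequenceRecord

__all__ = [
    "CaseParams",
    "SyntheticDesignCase",
    "generate_design_case",
    "load_published_primers",
    "load_primer_pairs_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CaseParams:
    """Shape of a synthetic design case.

    Defaults echo the geometry of a real rotifer COI design: a panel of 9
    sequences ~900 bp long, a forward primer site in the 20-50 bp region and
    a reverse site in the 860-880 bp region, with a 24-mer primer at each.
    ``core_substitution_prob`` (default 0.12) is the per-site, per-sequence
    substitution probability outside the planted windows — the order of the
    within-genus COI divergence the design must tolerate.
    ``site_polymorphisms`` lists (1-based column, allowed-base string)
    entries inside the planted windows; each listed column is drawn
    independently per sequence from its base set, emulating the polymorphic
    sites a degenerate primer position must cover.
    """

    n_sequences: int = 9
    length: int = 900
    forward_window: tuple[int, int] = (21, 44)
    reverse_window: tuple[int, int] = (857, 880)
    core_substitution_prob: float = 0.12
    site_polymorphisms: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        fw, rw = self.forward_window, self.reverse_window
        for lo, hi in (fw, rw):
            if not (1 <= lo <= hi <= self.length):
                raise ValueError(f"window {lo}:{hi} outside 1..{self.length}")
        if fw[1] >= rw[0]:
            raise ValueError("forward window must end before the reverse window starts")
        if not 0.0 <= self.core_substitution_prob <= 1.0:
            raise ValueError("core_substitution_prob must lie in [0, 1]")
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences")
        in_windows = set(range(fw[0], fw[1] + 1)) | set(range(rw[0], rw[1] + 1))
        for col, bases in self.site_polymorphisms:
            if col not in in_windows:
                raise ValueError(
                    f"polymorphic column {col} lies outside the planted windows"
                )
            if not bases or not set(bases.upper()) <= set("ACGT"):
                raise ValueError(f"bad base set {bases!r} for column {col}")


@dataclass(frozen=True)
class SyntheticDesignCase:
    """A generated panel plus its planted ground truth."""

    seed: int
    params: CaseParams
    ancestor: str
    block: AlignmentBlock
    truth_forward: Primer
    truth_reverse: Primer

    @property
    def records(self) -> tuple[SequenceRecord, ...]:
        return self.block.records


def _window_consensus(params: CaseParams, ancestor: str, window: tuple[int, int]) -> str:
    poly = {col: set(bases.upper()) for col, bases in params.site_polymorphisms}
    codes = []
    for col in range(window[0], window[1] + 1):
        codes.append(code_for_set(poly.get(col, {ancestor[col - 1]})))
    return "".join(codes)


def generate_design_case(
    params: CaseParams | None = None,
    seed: int = 0,
    *,
    ancestor: str | None = None,
) -> SyntheticDesignCase:
    """Generate a panel; bit-reproducible for fixed (params, seed, ancestor).

    Pass an explicit ``ancestor`` (e.g. from a previous case) with a fresh
    seed to regenerate an independent panel descending from the same
    ancestor — the setup for validating designed primers on sequences they
    were not designed from.
    """
    params = params or CaseParams()
    rng = np.random.default_rng(seed)
    n, L = params.n_sequences, params.length
    if ancestor is None:
        anc = _BASES[rng.integers(0, 4, size=L)]
        ancestor = anc.tobytes().decode()
    else:
        if len(ancestor) != L or not set(ancestor) <= set("ACGT"):
            raise ValueError("ancestor must be a plain ACGT string of the case length")
        anc = np.frombuffer(ancestor.encode(), dtype=np.uint8).copy()
    panel = np.tile(anc, (n, 1))

    in_window = np.zeros(L, dtype=bool)
    for lo, hi in (params.forward_window, params.reverse_window):
        in_window[lo - 1 : hi] = True

    # core substitutions: uniform over the 3 alternative bases
    anc_idx = np.searchsorted(_BASES, anc)
    mutate = (rng.random((n, L)) < params.core_substitution_prob) & ~in_window
    shift = rng.integers(1, 4, size=(n, L))
    mutated_idx = (np.tile(anc_idx, (n, 1)) + shift) % 4
    panel[mutate] = _BASES[mutated_idx[mutate]]

    # planted polymorphisms: each listed column drawn per sequence from its set
    for col, bases in params.site_polymorphisms:
        pool = np.frombuffer(bases.upper().encode(), dtype=np.uint8)
        panel[:, col - 1] = pool[rng.integers(0, len(pool), size=n)]

    # the planted windows are the ground truth, so they must be *maximal*
    # conserved runs: force each column immediately flanking a window to show
    # at least two bases, otherwise the conserved region would extend past
    # the window and the truth would be ambiguous; skipped for a deliberately
    # invariant panel (core_substitution_prob 0)
    flanks: list[int] = []
    if params.core_substitution_prob > 0.0:
        for lo, hi in (params.forward_window, params.reverse_window):
            flanks.extend(
                c for c in (lo - 1, hi + 1) if 1 <= c <= L and not in_window[c - 1]
            )
    for col in flanks:
        if len(set(panel[:, col - 1].tolist())) == 1:
            row = int(rng.integers(0, n))
            cur = int(np.searchsorted(_BASES, panel[row, col - 1]))
            panel[row, col - 1] = _BASES[(cur + int(rng.integers(1, 4))) % 4]

    width = len(str(n))
    records = tuple(
        SequenceRecord(id=f"seq{str(i + 1).zfill(width)}", sequence=panel[i].tobytes().decode())
        for i in range(n)
    )
    fwd_cons = _window_consensus(params, ancestor, params.forward_window)
    rev_cons = _window_consensus(params, ancestor, params.reverse_window)
    return SyntheticDesignCase(
        seed=seed,
        params=params,
        ancestor=ancestor,
        block=AlignmentBlock(records),
        truth_forward=Primer("truth_F", fwd_cons, "forward"),
        truth_reverse=Primer("truth_R", reverse_complement(rev_cons), "reverse"),
    )


def load_primer_pairs_tsv(path) -> list[PrimerPair]:
    """Read primer pairs from a TSV with header.

    Required columns: ``pair_name``, ``forward_seq``, ``reverse_seq``;
    optional ``forward_name``/``reverse_name`` (default <pair>_F / <pair>_R).
    """
    pairs: list[PrimerPair] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"pair_name", "forward_seq", "reverse_seq"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"pairs file needs columns {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            name = row["pair_name"]
            pairs.append(
                PrimerPair(
                    name=name,
                    forward=Primer(
                        row.get("forward_name") or f"{name}_F", row["forward_seq"], "forward"
                    ),
                    reverse=Primer(
                        row.get("reverse_name") or f"{name}_R", row["reverse_seq"], "reverse"
                    ),
                )
            )
    if not pairs:
        raise ValueError(f"no primer pairs found in {path}")
    return pairs


def load_published_primers() -> list[PrimerPair]:
    """The three packaged rotifer-COI primer pairs.

    30F/885R (the new degenerate pair), LCO2198/HCO1490 (the Folmer
    universal pair) and dgLCO/dgHCO (the degenerate Folmer derivative), as
    published.
    """
    ref = resources.files("barcodeprimer").joinpath("data/published_pairs.tsv")
    with resources.as_file(ref) as path:
        return load_primer_pairs_tsv(path)
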