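"""In-silico PCR: primer binding-site search and amplicon prediction.

A primer binds a template wherever it can be slid along the plus strand
with few enough mismatches under IUPAC intersection matching.  Mismatches
are weighted by position: the 3' terminus is where the polymerase extends,
so mismatches there are disruptive while 5' mismatches are usually
tolerated.  The policy encodes that as a hard cap on mismatches inside a
3'-terminal window on top of a total-mismatch cap.

Forward primers are scanned as written; reverse primers are scanned as
their reverse complement on the plus strand and reported as minus-strand
sites.  An amplicon is a plus-strand forward site upstream of a
minus-strand reverse site with an in-range product length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .iupac import Primer, match_base, reverse_complement
from .seqio import SequenceRecord

__all__ = [
    "MismatchPolicy",
    "BindingSite",
    "AmpliconPrediction",
    "PrimerPair",
    "find_binding_sites",
    "predict_amplicons",
    "success_matrix",
]


@dataclass(frozen=True)
class MismatchPolicy:
    """Positional mismatch tolerance for binding-site calls.

    ``max_total_mismatches``       cap over the whole primer (default 3).
    ``three_prime_window``         how many 3'-terminal primer bases form
                                   the anchor (default 5).
    ``max_three_prime_mismatches`` cap inside the anchor (default 0: the 3'
                                   end must match perfectly).
    """

    max_total_mismatches: int = 3
    three_prime_window: int = 5
    max_three_prime_mismatches: int = 0

    def __post_init__(self):
        if not 0 <= self.max_three_prime_mismatches <= self.max_total_mismatches:
            raise ValueError(
                "need 0 <= max_three_prime_mismatches <= max_total_mismatches"
            )
        if self.three_prime_window < 0:
            raise ValueError("three_prime_window must be >= 0")


@dataclass(frozen=True)
class BindingSite:
    """One primer placement on a template.

    Coordinates are 1-based inclusive on the ungapped template plus strand.
    ``mismatch_mask`` runs 5'->3' along the *primer* (True = mismatch), so
    for a minus-strand site it is reversed relative to template order.
    """

    record_id: str
    strand: str  # "plus" | "minus"
    start: int
    end: int
    total_mismatches: int
    three_prime_mismatches: int
    mismatch_mask: tuple[bool, ...]


@dataclass(frozen=True)
class AmpliconPrediction:
    """A compatible site pair and its product length (5' end of the forward
    primer through the 5' end of the reverse primer, inclusive)."""

    record_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    product_length: int


class PrimerPair(NamedTuple):
    name: str
    forward: Primer
    reverse: Primer


def find_binding_sites(
    primer: Primer,
    template: SequenceRecord,
    policy: MismatchPolicy | None = None,
) -> list[BindingSite]:
    """All placements of ``primer`` on ``template`` the policy admits.

    The template must be gap-free (de-gap aligned input first, see
    seqio.degap).  Sites are sorted by (total mismatches, start).  The 3'
    window is counted on the primer's own 3' terminus: for a minus-strand
    site that is the template-leftmost end of the match, facing into the
    amplicon.
    """
    policy = policy or MismatchPolicy()
    seq = template.sequence
    if "-" in seq:
        raise ValueError(
            f"template {template.id!r} contains gaps; de-gap before scanning"
        )
    L = len(primer.sequence)
    if L > len(seq):
        raise ValueError(
            f"primer {primer.name!r} ({L} nt) is longer than template "
            f"{template.id!r} ({len(seq)} nt)"
        )
    if primer.orientation == "forward":
        query = primer.sequence
        strand = "plus"
        # primer 3' end sits at the template-rightmost end of the window
        three_prime_idx = range(max(0, L - policy.three_prime_window), L)
    else:
        query = reverse_complement(primer.sequence)
        strand = "minus"
        # reverse-complemented, the primer 3' end is template-leftmost
        three_prime_idx = range(0, min(policy.three_prime_window, L))
    three_prime_set = frozenset(three_prime_idx)
    sites: list[BindingSite] = []
    for offset in range(len(seq) - L + 1):
        mask = [not match_base(seq[offset + k], query[k]) for k in range(L)]
        total = sum(mask)
        if total > policy.max_total_mismatches:
            continue
        three = sum(mask[k] for k in three_prime_set)
        if three > policy.max_three_prime_mismatches:
            continue
        if strand == "minus":
            mask.reverse()  # report 5'->3' along the primer
        sites.append(
            BindingSite(
                record_id=template.id,
                strand=strand,
                start=offset + 1,
                end=offset + L,
                total_mismatches=total,
                three_prime_mismatches=three,
                mismatch_mask=tuple(mask),
            )
        )
    sites.sort(key=lambda s: (s.total_mismatches, s.start))
    return sites


def predict_amplicons(
    forward: Primer,
    reverse: Primer,
    template: SequenceRecord,
    policy: MismatchPolicy | None = None,
    length_range: tuple[int, int] = (400, 1000),
) -> list[AmpliconPrediction]:
    """Every compatible forward/reverse site pair on one template.

    A pair is compatible when the plus-strand forward site lies wholly
    upstream of the minus-strand reverse site and the product length
    (reverse-site end - forward-site start + 1) falls within
    ``length_range``.  All combinations are reported; no "best" site is
    selected.
    """
    policy = policy or MismatchPolicy()
    lo, hi = length_range
    f_sites = find_binding_sites(forward, template, policy)
    r_sites = find_binding_sites(reverse, template, policy)
    out: list[AmpliconPrediction] = []
    for f in f_sites:
        for r in r_sites:
            if f.end >= r.start:
                continue
            product = r.end - f.start + 1
            if lo <= product <= hi:
                out.append(AmpliconPrediction(template.id, f, r, product))
    out.sort(key=lambda a: (a.forward_site.start, a.reverse_site.start))
    return out


def success_matrix(
    pairs: Iterable[PrimerPair],
    references: Sequence[SequenceRecord],
    grouping: Mapping[str, str] | None = None,
    policy: MismatchPolicy | None = None,
    length_range: tuple[int, int] = (400, 1000),
) -> pd.DataFrame:
    """Per-(pair, group) in-silico amplification success rates.

    A record counts as amplified by a pair when it yields at least one
    predicted amplicon.  ``grouping`` maps record id -> group label (e.g.
    genus); unmapped records form singleton groups under their own id.  The
    result is a tidy table with one row per (pair, group) plus an
    ``overall`` row per pair; ``success`` = amplified / n_records.
    """
    references = list(references)
    if not references:
        raise ValueError("empty reference set")
    policy = policy or MismatchPolicy()
    grouping = dict(grouping or {})
    rows: list[dict] = []
    for pair in pairs:
        amplified: dict[str, bool] = {}
        for rec in references:
            amplified[rec.id] = bool(
                predict_amplicons(pair.forward, pair.reverse, rec, policy, length_range)
            )
        by_group: dict[str, list[str]] = {}
        for rec in references:
            by_group.setdefault(grouping.get(rec.id, rec.id), []).append(rec.id)
        for group in sorted(by_group):
            ids = by_group[group]
            n_ok = sum(amplified[i] for i in ids)
            rows.append(
                dict(pair=pair.name, group=group, n_records=len(ids),
                     n_amplified=n_ok, success=n_ok / len(ids))
            )
        n_ok = sum(amplified.values())
        rows.append(
            dict(pair=pair.name, group="overall", n_records=len(references),
                 n_amplified=n_ok, success=n_ok / len(references))
        )
    return pd.DataFrame(rows, columns=["pair", "group", "n_records", "n_amplified", "success"])
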