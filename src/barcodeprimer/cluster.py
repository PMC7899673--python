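"""Greedy identity-threshold dereplication of a reference sequence set.

Collapses near-identical reference sequences (e.g. all COI barcodes of a
taxon pulled from a public database) into clusters represented by their
longest member, the centroid.  The strategy is the classic greedy
incremental one: sort by descending length, and let each sequence join the
first centroid it is similar enough to, else found a new cluster.

Identity between two gap-free sequences is computed from a global
Needleman-Wunsch alignment with fixed scoring (match +1, mismatch -1,
gap -2, linear) and a deterministic traceback, as exact matches divided by
either the number of aligned columns (default) or the shorter sequence
length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .iupac import validate_sequence
from .seqio import SequenceRecord

__all__ = ["Cluster", "needleman_wunsch", "global_identity", "dereplicate"]

MATCH, MISMATCH, GAP = 1, -1, -2


def needleman_wunsch(a: str, b: str) -> tuple[str, str, int]:
    """Optimal global alignment of two plain sequences.

    Returns (aligned_a, aligned_b, score) under match +1 / mismatch -1 /
    gap -2 (linear).  Ties in the traceback prefer diagonal, then a gap in
    ``b`` (up), then a gap in ``a`` (left), so the result is deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    score[0, :] = GAP * np.arange(m + 1)
    score[:, 0] = GAP * np.arange(n + 1)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(aa[:, None] == bb[None, :], MATCH, MISMATCH).astype(np.int32)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + GAP
        best = np.maximum(diag, up)
        row = score[i]
        prev = row[0]
        # the left-dependency forces a sequential pass within the row
        for j in range(1, m + 1):
            prev = max(best[j - 1], prev + GAP)
            row[j] = prev
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + GAP:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(score[n, m])


def global_identity(a: str, b: str, *, denominator: str = "alignment") -> float:
    """Fraction of identical positions under optimal global alignment.

    ``denominator="alignment"`` divides exact matches by the number of
    aligned columns (gap columns included); ``"shorter"`` divides by the
    shorter sequence length, the convention cd-hit-like tools use.
    Symmetric in its arguments; returns a value in [0, 1].
    """
    a = validate_sequence(a, context="sequence a")
    b = validate_sequence(b, context="sequence b")
    aln_a, aln_b, _ = needleman_wunsch(a, b)
    matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != "-")
    if denominator == "alignment":
        denom = len(aln_a)
    elif denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return matches / denom


@dataclass(frozen=True)
class Cluster:
    """A centroid plus its members with their identity to the centroid.

    The centroid is included among the members (identity 1.0), so the
    members of all clusters partition the input.
    """

    centroid: SequenceRecord
    members: tuple[tuple[SequenceRecord, float], ...]


def dereplicate(
    records: Sequence[SequenceRecord],
    threshold: float = 0.9,
    *,
    denominator: str = "alignment",
) -> list[Cluster]:
    """Greedy longest-first clustering at an identity threshold.

    Records are visited by descending length (ties: lexicographic id); each
    joins the first existing centroid with identity >= ``threshold``, else
    founds a new cluster.  Deterministic; clusters are disjoint and cover
    the input.  An empty input yields an empty list.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0.5, 1.0], got {threshold}")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    centroids: list[SequenceRecord] = []
    membership: list[list[tuple[SequenceRecord, float]]] = []
    for rec in ordered:
        for ci, centroid in enumerate(centroids):
            ident = global_identity(rec.sequence, centroid.sequence, denominator=denominator)
            if ident >= threshold:
                membership[ci].append((rec, ident))
                break
        else:
            centroids.append(rec)
            membership.append([(rec, 1.0)])
    return [
        Cluster(centroid=c, members=tuple(mem))
        for c, mem in zip(centroids, membership)
    ]
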