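"""Per-gene sensitivity counts, ranking, and equal-area centering.

The sensitivity of a gene to chemical exposures is measured as its number
of distinct chemical-gene interactions.  Because every count is positive,
the ranked list is unsuitable for a signed enrichment walk; a single
constant is therefore subtracted from every count so that the positive and
negative deviations have equal total area.  The difference of those areas
is ``sum(x_i - c)``, so the unique equalizing constant is the arithmetic
mean of the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence, Union

import numpy as np

from .io import _open_maybe
from .records import Direction, InteractionRecord

StreamOrPath = Union[str, Path, IO[str]]


@dataclass(frozen=True)
class GeneSensitivity:
    """Interaction counts for one gene, split by direction of change."""

    gene: str
    n_suppressive: int
    n_activating: int
    n_unspecified: int

    @property
    def n_total(self) -> int:
        return self.n_suppressive + self.n_activating + self.n_unspecified


@dataclass
class RankedList:
    """Genes ordered by centered sensitivity score.

    ``centered[i] = raw[i] - shift`` for every gene; the centered scores sum
    to zero (within floating tolerance), which is the equal-area guarantee.
    Order is descending by centered score with ties broken by gene symbol.
    """

    genes: list[str]
    raw: np.ndarray
    centered: np.ndarray
    shift: float

    def __len__(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except AttributeError:
            object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})
            return self._index[gene]

    def universe(self) -> frozenset[str]:
        return frozenset(self.genes)


def count_interactions(records: Sequence[InteractionRecord]) -> list[GeneSensitivity]:
    """Tally per-gene interaction counts from a deduplicated record list.

    The caller is responsible for deduplicating first; on duplicated input
    the totals double-count.  Returns one row per distinct gene, in
    first-seen order; the totals over genes sum to ``len(records)``.
    """
    counts: dict[str, list[int]] = {}
    for r in records:
        row = counts.setdefault(r.gene, [0, 0, 0])
        if r.direction is Direction.DECREASE:
            row[0] += 1
        elif r.direction is Direction.INCREASE:
            row[1] += 1
        else:
            row[2] += 1
    return [
        GeneSensitivity(gene, sup, act, unspec)
        for gene, (sup, act, unspec) in counts.items()
    ]


_METRICS = ("total", "activating", "suppressive")


def rank_genes(
    table: Sequence[GeneSensitivity], metric: str = "total"
) -> list[tuple[str, int]]:
    """Order genes descending by the chosen count, ties by symbol ascending."""
    if not table:
        raise ValueError("sensitivity table is empty")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    genes = [row.gene for row in table]
    if len(set(genes)) != len(genes):
        raise ValueError("sensitivity table contains duplicate genes")
    key = {
        "total": lambda r: r.n_total,
        "activating": lambda r: r.n_activating,
        "suppressive": lambda r: r.n_suppressive,
    }[metric]
    ordered = sorted(table, key=lambda r: (-key(r), r.gene))
    return [(r.gene, key(r)) for r in ordered]


def center_scores(ranked: Sequence[tuple[str, float]]) -> RankedList:
    """Subtract the equal-area constant (the mean) from every raw score.

    Requires at least two genes and a non-constant score vector; a constant
    ranking carries no signal and would center to all zeros.
    """
    if len(ranked) < 2:
        raise ValueError("need at least two genes to center")
    genes = [g for g, _ in ranked]
    raw = np.asarray([s for _, s in ranked], dtype=float)
    if np.all(raw == raw[0]):
        raise ValueError("all raw scores are equal; centered ranking is degenerate")
    shift = float(raw.mean())
    centered = raw - shift
    return RankedList(genes=genes, raw=raw, centered=centered, shift=shift)


def write_counts(table: Sequence[GeneSensitivity], stream: StreamOrPath) -> None:
    """Write the per-gene counts table (gene, suppressive, activating, not specified, total)."""
    fh, close = _open_maybe(stream, "w")
    try:
        fh.write("gene\tsuppressive\tactivating\tnot specified\ttotal\n")
        for row in table:
            fh.write(
                f"{row.gene}\t{row.n_suppressive}\t{row.n_activating}"
                f"\t{row.n_unspecified}\t{row.n_total}\n"
            )
    finally:
        if close:
            fh.close()


def read_counts(stream: StreamOrPath) -> list[GeneSensitivity]:
    fh, close = _open_maybe(stream)
    try:
        header = next(fh)
        cols = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
        idx = {c: i for i, c in enumerate(cols)}
        for col in ("gene", "suppressive", "activating", "not specified"):
            if col not in idx:
                raise ValueError(f"missing column {col!r} in counts table")
        rows = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(
                GeneSensitivity(
                    gene=parts[idx["gene"]].upper(),
                    n_suppressive=int(parts[idx["suppressive"]]),
                    n_activating=int(parts[idx["activating"]]),
                    n_unspecified=int(parts[idx["not specified"]]),
                )
            )
        return rows
    finally:
        if close:
            fh.close()


def write_rnk(ranked: RankedList, stream: StreamOrPath) -> None:
    """Write the two-column preranked file (gene, centered score), order preserved.

    Scores are printed with 12 significant digits so an external stable sort
    on column 2 reproduces the in-memory order.
    """
    fh, close = _open_maybe(stream, "w")
    try:
        for gene, score in zip(ranked.genes, ranked.centered):
            fh.write(f"{gene}\t{score:.12g}\n")
    finally:
        if close:
            fh.close()


def read_rnk(stream: StreamOrPath) -> list[tuple[str, float]]:
    fh, close = _open_maybe(stream)
    try:
        out = []
        for line in fh:
            if not line.strip():
                continue
            gene, score = line.rstrip("\n").split("\t")
            out.append((gene, float(score)))
        return out
    finally:
        if close:
            fh.close()
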