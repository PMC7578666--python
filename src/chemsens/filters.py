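"""Validation, filtering and deduplication of interaction records.

The pipeline keeps only experiments from human, mouse and rat, drops genes
that are not present in all three genomes (so a gene is one cross-species
entity), and collapses repeated reports of the same (study, biological
model, chemical, gene) combination to a single interaction line.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .records import (
    AnnotationViolation,
    DedupReport,
    Direction,
    GenePresenceTable,
    InteractionRecord,
    Taxon,
    is_vocabulary_term,
    normalize_use_term,
)


def validate_annotations(
    records: Sequence[InteractionRecord],
) -> list[AnnotationViolation]:
    """Check every record's use annotations against the 11-term vocabulary.

    A conforming record carries one to three distinct vocabulary terms.
    Violations are returned as data (one per offending record), never raised:
    an empty list means the whole table conforms.
    """
    violations: list[AnnotationViolation] = []
    for i, rec in enumerate(records):
        n = len(rec.uses)
        if n == 0:
            violations.append(AnnotationViolation(i, rec, "no use annotation"))
            continue
        if n > 3:
            violations.append(
                AnnotationViolation(i, rec, f"{n} use terms exceed the up-to-3 rule")
            )
            continue
        normalized = [normalize_use_term(u) for u in rec.uses]
        if len(set(normalized)) != n:
            violations.append(AnnotationViolation(i, rec, "duplicate use terms"))
            continue
        unknown = [u for u, nu in zip(rec.uses, normalized) if not is_vocabulary_term(nu)]
        if unknown:
            violations.append(
                AnnotationViolation(i, rec, f"unknown use term(s): {', '.join(unknown)}")
            )
    return violations


def filter_taxa(
    records: Sequence[InteractionRecord], allowed: Iterable[Taxon]
) -> list[InteractionRecord]:
    """Order-preserving subset of records whose taxon is in ``allowed``."""
    allowed = frozenset(allowed)
    if not allowed:
        raise ValueError("allowed taxa set must be nonempty")
    return [r for r in records if r.taxon in allowed]


def filter_shared_genes(
    records: Sequence[InteractionRecord], presence: GenePresenceTable
) -> tuple[list[InteractionRecord], set[str]]:
    """Drop records whose gene is absent from any of the three genomes.

    Returns the kept records (order preserved) and the set of removed gene
    symbols.  A gene missing from the presence table entirely is an error —
    the caller must supply a complete table rather than have genes silently
    kept or dropped.
    """
    kept: list[InteractionRecord] = []
    removed: set[str] = set()
    for r in records:
        if r.gene not in presence:
            raise KeyError(f"gene {r.gene} missing from the gene-presence table")
        if presence.shared(r.gene):
            kept.append(r)
        else:
            removed.add(r.gene)
    return kept, removed


def deduplicate(
    records: Sequence[InteractionRecord],
) -> tuple[list[InteractionRecord], DedupReport]:
    """Collapse records sharing the (gene, chemical, pmid, taxon) key.

    The key is the unique-interaction identity: one original study (PMID),
    one biological model (taxon), one chemical, one gene.  Direction is not
    part of the key; if the collapsed group disagrees on direction, the
    surviving record's direction becomes unspecified ("1") and the conflict
    is counted.  First-seen order is preserved.
    """
    by_key: dict[tuple[str, str, int, Taxon], int] = {}
    unique: list[InteractionRecord] = []
    n_collapsed = 0
    n_conflicts = 0
    conflicted: set[int] = set()
    for r in records:
        key = (r.gene, r.chemical, r.pmid, r.taxon)
        pos = by_key.get(key)
        if pos is None:
            by_key[key] = len(unique)
            unique.append(r)
        else:
            n_collapsed += 1
            survivor = unique[pos]
            if survivor.direction != r.direction and pos not in conflicted:
                conflicted.add(pos)
                n_conflicts += 1
                unique[pos] = InteractionRecord(
                    chemical=survivor.chemical,
                    gene=survivor.gene,
                    direction=Direction.UNSPECIFIED,
                    taxon=survivor.taxon,
                    pmid=survivor.pmid,
                    uses=survivor.uses,
                    use_description=survivor.use_description,
                )
    report = DedupReport(
        n_input=len(records),
        n_unique=len(unique),
        n_collapsed=n_collapsed,
        n_direction_conflicts=n_conflicts,
    )
    return unique, report


def subset_by_use(
    records: Sequence[InteractionRecord], term: str
) -> list[InteractionRecord]:
    """Subset of records whose chemical carries the given use term.

    ``term`` must be one of the 11 vocabulary terms (case-insensitive).
    """
    normalized = normalize_use_term(term)
    if not is_vocabulary_term(normalized):
        raise ValueError(f"unknown use term {term!r}")
    return [
        r for r in records if any(normalize_use_term(u) == normalized for u in r.uses)
    ]
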