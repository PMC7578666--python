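"""Core domain types for chemical-gene interaction data.

One :class:`InteractionRecord` corresponds to one reported significant change
in a gene's expression following exposure to a chemical compound, in one
study and one biological model (taxon).  The controlled vocabulary of
chemical-use annotations and the per-species gene-presence table live here
as well, because every downstream filtering step is defined in terms of
these types.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class Direction(str, enum.Enum):
    """Direction of the expression change caused by an exposure.

    ``INCREASE`` ("+") - expression increase; ``DECREASE`` ("-") -
    expression decrease; ``UNSPECIFIED`` ("1") - a significant change whose
    direction the source did not specify.
    """

    INCREASE = "+"
    DECREASE = "-"
    UNSPECIFIED = "1"


class Taxon(str, enum.Enum):
    """The three model organisms whose experiments are retained."""

    HOMO = "Homo"
    MUS = "Mus"
    RATTUS = "Rattus"


#: The 11-term controlled vocabulary of major chemical uses.  Each chemical
#: carries one to three of these terms.
USE_VOCABULARY: frozenset[str] = frozenset(
    {
        "pharmaceutical",
        "recreational drug",
        "research",
        "warfare",
        "endobiotic",
        "agricultural",
        "cosmetics",
        "environment",
        "food components",
        "industrial",
        "pollutant",
    }
)


def normalize_use_term(term: str) -> str:
    """Whitespace-collapse and lowercase a use-annotation term."""
    return " ".join(term.split()).lower()


def is_vocabulary_term(term: str) -> bool:
    """Case/whitespace-insensitive membership test against the 11-term vocabulary."""
    return normalize_use_term(term) in USE_VOCABULARY


@dataclass(frozen=True)
class InteractionRecord:
    """One chemical-gene interaction line.

    Parameters
    ----------
    chemical : str
        Chemical name (nonempty free text).
    gene : str
        Gene symbol, uppercased canonical form.
    direction : Direction
        Direction of the expression change.
    taxon : Taxon
        Organism of the experiment.
    pmid : int
        PubMed identifier of the source study (positive).
    uses : tuple of str
        One to three use-annotation terms for the chemical.
    use_description : str
        Free-text description of the chemical's major uses (may be empty).
    """

    chemical: str
    gene: str
    direction: Direction
    taxon: Taxon
    pmid: int
    uses: tuple[str, ...]
    use_description: str = ""


@dataclass(frozen=True)
class AnnotationViolation:
    """One record's breach of the use-annotation rules (data, not an exception)."""

    index: int
    record: InteractionRecord
    reason: str


@dataclass
class DedupReport:
    """Bookkeeping for collapsing repeated (gene, chemical, pmid, taxon) lines."""

    n_input: int
    n_unique: int
    n_collapsed: int
    n_direction_conflicts: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_unique + self.n_collapsed:
            raise ValueError("n_input must equal n_unique + n_collapsed")
        if self.n_direction_conflicts > self.n_collapsed:
            raise ValueError("n_direction_conflicts cannot exceed n_collapsed")


class GenePresenceTable:
    """Per-gene presence/absence flags in the Homo, Mus and Rattus genomes.

    Keys are uppercased gene symbols; each value is a ``(homo, mus, rattus)``
    triple of booleans.
    """

    def __init__(self, flags: Mapping[str, tuple[bool, bool, bool]] | None = None):
        self._flags: dict[str, tuple[bool, bool, bool]] = {}
        if flags:
            for gene, triple in flags.items():
                self.add(gene, triple)

    def add(self, gene: str, triple: Iterable[bool]) -> None:
        triple = tuple(bool(x) for x in triple)
        if len(triple) != 3:
            raise ValueError(f"presence flags for {gene!r} must be a triple")
        key = gene.upper()
        if key in self._flags and self._flags[key] != triple:
            raise ValueError(f"conflicting presence flags for gene {key}")
        self._flags[key] = triple

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self._flags

    def __getitem__(self, gene: str) -> tuple[bool, bool, bool]:
        return self._flags[gene.upper()]

    def __len__(self) -> int:
        return len(self._flags)

    def genes(self) -> list[str]:
        return list(self._flags)

    def shared(self, gene: str) -> bool:
        """True iff the gene is present in all three genomes."""
        return all(self._flags[gene.upper()])


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (e.g. Hallmark, KEGG, Reactome).

    ``sets`` maps set name -> ``(description, frozenset of uppercased symbols)``.
    """

    collection_name: str
    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        cleaned = frozenset(m.upper() for m in members if m)
        if not cleaned:
            raise ValueError(f"gene set {name!r} has no members")
        self.sets[name] = (description, cleaned)

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return (
            self.collection_name == other.collection_name and self.sets == other.sets
        )
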