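"""Synthetic CTD-like data with planted pathway-sensitivity structure.

Real per-gene interaction counts are strongly heavy-tailed: a small number
of highly chemically responsive genes accumulate thousands of reported
interactions while most genes have few.  The generator reproduces that
shape with a latent-rate model: each gene g receives a log-normal latent
sensitivity lambda_g (mean ``base_rate``, log-scale spread ``dispersion``)
and emits Poisson(lambda_g) interaction lines.  Genes belonging to a
planted "high" set have lambda multiplied by the effect factor; planted
"low" sets are divided by it.  Emitted tables use exactly the interchange
formats the readers consume, are born deduplicated, and come with a
ground-truth sidecar so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import (
    USE_VOCABULARY,
    Direction,
    GenePresenceTable,
    GeneSetCollection,
    InteractionRecord,
    Taxon,
)

_TAXA = (Taxon.HOMO, Taxon.MUS, Taxon.RATTUS)
# direction weights are ordered (increase "+", decrease "-", unspecified "1")
_DIRECTIONS = (Direction.INCREASE, Direction.DECREASE, Direction.UNSPECIFIED)
_USE_TERMS = tuple(sorted(USE_VOCABULARY))


@dataclass
class PlantedSet:
    """A gene set with a shifted latent sensitivity.

    ``direction="high"`` multiplies members' latent rates by
    ``effect_factor`` (the set should surface as most sensitive);
    ``"low"`` divides (least sensitive).
    """

    name: str
    size: int
    effect_factor: float = 3.0
    direction: str = "high"

    def __post_init__(self) -> None:
        if self.effect_factor < 1:
            raise ValueError("effect_factor must be >= 1")
        if self.direction not in ("high", "low"):
            raise ValueError("direction must be 'high' or 'low'")


def default_planted_sets() -> list[PlantedSet]:
    return [
        PlantedSet("PLANTED_HIGH_1", 50, 3.0, "high"),
        PlantedSet("PLANTED_HIGH_2", 50, 3.0, "high"),
        PlantedSet("PLANTED_HIGH_3", 50, 3.0, "high"),
        PlantedSet("PLANTED_LOW_1", 50, 3.0, "low"),
        PlantedSet("PLANTED_LOW_2", 50, 3.0, "low"),
    ]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the scale of the real data: a mean of 34 interactions
    per gene (the deposited tables carry 591,084 interactions over 17,338
    genes, about 34 per gene) with log-scale dispersion 1.0 for the heavy
    right tail, three planted-high and two planted-low sets of 50 genes at
    effect factor 3 among 40 null sets, a 2,000-gene universe, and taxon /
    direction mixes dominated by human and by the two specified directions.

    ``direction_weights`` is ordered (increase "+", decrease "-",
    unspecified "1"); ``taxa_weights`` is ordered (Homo, Mus, Rattus).
    """

    n_genes: int = 2000
    n_chemicals: int = 300
    base_rate: float = 34.0
    dispersion: float = 1.0
    planted_sets: list[PlantedSet] = field(default_factory=default_planted_sets)
    n_null_sets: int = 40
    null_set_size: int = 50
    taxa_weights: tuple[float, float, float] = (0.45, 0.35, 0.20)
    direction_weights: tuple[float, float, float] = (0.40, 0.40, 0.20)
    presence_holdout: float = 0.0  # fraction of genes marked absent in one genome
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate <= 0 or self.dispersion <= 0:
            raise ValueError("base_rate and dispersion must be > 0")
        for w in (self.taxa_weights, self.direction_weights):
            if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1) > 1e-9:
                raise ValueError("weights must be 3 nonnegative reals summing to 1")
        if sum(ps.size for ps in self.planted_sets) > self.n_genes:
            raise ValueError("planted set sizes exceed n_genes")
        if not 0 <= self.presence_holdout < 1:
            raise ValueError("presence_holdout must be in [0, 1)")


@dataclass
class GroundTruth:
    """Latent state of one generated universe."""

    genes: list[str]
    lam: np.ndarray  # per-gene latent sensitivity, > 0
    planted: dict[str, PlantedSet]
    membership: dict[str, list[str]]  # planted set name -> member genes

    def planted_genes(self) -> frozenset[str]:
        return frozenset(g for members in self.membership.values() for g in members)

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": self.genes,
                "lambda": [float(x) for x in self.lam],
                "planted": {
                    name: {
                        "size": ps.size,
                        "effect_factor": ps.effect_factor,
                        "direction": ps.direction,
                        "members": self.membership[name],
                    }
                    for name, ps in self.planted.items()
                },
            }
        )


_STREAMS = {"universe": 0, "interactions": 1, "collections": 2}


def _rng(config: GeneratorConfig, label: str) -> np.random.Generator:
    # fixed substream per stage so e.g. regenerating collections alone is stable
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[label],))
    )


def gen_universe(config: GeneratorConfig) -> GroundTruth:
    """Draw latent sensitivities and assign planted-set membership.

    lambda_g = base_rate * exp(dispersion * Z - dispersion^2 / 2) with
    Z ~ N(0,1), so E[lambda] = base_rate for every dispersion.  Planted
    members are disjoint blocks of the gene universe; their lambda is
    multiplied (high) or divided (low) by the effect factor.
    """
    rng = _rng(config, "universe")
    width = len(str(config.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    z = rng.standard_normal(config.n_genes)
    lam = config.base_rate * np.exp(config.dispersion * z - config.dispersion**2 / 2)

    order = rng.permutation(config.n_genes)
    membership: dict[str, list[str]] = {}
    planted: dict[str, PlantedSet] = {}
    cursor = 0
    for ps in config.planted_sets:
        idx = order[cursor : cursor + ps.size]
        cursor += ps.size
        if ps.direction == "high":
            lam[idx] *= ps.effect_factor
        else:
            lam[idx] /= ps.effect_factor
        members = sorted(genes[i] for i in idx)
        membership[ps.name] = members
        planted[ps.name] = ps
    return GroundTruth(genes=genes, lam=lam, planted=planted, membership=membership)


def gen_interactions(
    truth: GroundTruth, config: GeneratorConfig
) -> tuple[list[InteractionRecord], GenePresenceTable]:
    """Emit Poisson(lambda_g) interaction lines per gene, plus a presence table.

    Each line draws a chemical uniformly, a taxon and a direction from their
    weight vectors, a synthetic PMID, and 1-3 legal use terms.  Collisions on
    the (gene, chemical, pmid, taxon) dedup key are regenerated, so the
    emitted table is born exactly deduplicated.  The presence table marks
    every gene present in all three genomes except a ``presence_holdout``
    fraction, which get one flag cleared (for exercising the shared-genome
    filter).
    """
    rng = _rng(config, "interactions")
    counts = rng.poisson(truth.lam)
    cwidth = len(str(config.n_chemicals))
    chemicals = [f"CHEM{i + 1:0{cwidth}d}" for i in range(config.n_chemicals)]
    use_count_p = (0.5, 0.35, 0.15)  # P(1), P(2), P(3) use terms per chemical
    chem_uses: list[tuple[str, ...]] = []
    for _ in chemicals:
        k = rng.choice(3, p=use_count_p) + 1
        chem_uses.append(tuple(sorted(rng.choice(len(_USE_TERMS), size=k, replace=False))))
    records: list[InteractionRecord] = []
    for gi, gene in enumerate(truth.genes):
        k = int(counts[gi])
        if k == 0:
            continue
        seen: set[tuple[int, int, int]] = set()
        while len(seen) < k:
            need = k - len(seen)
            chem_i = rng.integers(0, config.n_chemicals, size=need)
            taxon_i = rng.choice(3, size=need, p=config.taxa_weights)
            pmid = rng.integers(10_000_000, 35_000_000, size=need)
            for c, t, p in zip(chem_i, taxon_i, pmid):
                seen.add((int(c), int(t), int(p)))
        dir_i = rng.choice(3, size=k, p=config.direction_weights)
        for (c, t, p), d in zip(sorted(seen), dir_i):
            records.append(
                InteractionRecord(
                    chemical=chemicals[c],
                    gene=gene,
                    direction=_DIRECTIONS[d],
                    taxon=_TAXA[t],
                    pmid=int(p),
                    uses=tuple(_USE_TERMS[u] for u in chem_uses[c]),
                    use_description=f"synthetic uses of {chemicals[c]}",
                )
            )
    presence = GenePresenceTable()
    n_holdout = int(round(config.presence_holdout * config.n_genes))
    holdout = set(rng.choice(config.n_genes, size=n_holdout, replace=False).tolist())
    for gi, gene in enumerate(truth.genes):
        if gi in holdout:
            missing = int(rng.integers(0, 3))
            flags = [True, True, True]
            flags[missing] = False
            presence.add(gene, flags)
        else:
            presence.add(gene, (True, True, True))
    return records, presence


def gen_collections(
    truth: GroundTruth, config: GeneratorConfig, collection_name: str = "SYNTHETIC"
) -> tuple[GeneSetCollection, dict[str, str]]:
    """Planted sets plus ``n_null_sets`` random sets of non-planted genes.

    Returns the collection and a label map: set name -> "planted_high" /
    "planted_low" / "null".  Null sets are drawn uniformly (without
    replacement within a set) from genes outside every planted set.
    """
    rng = _rng(config, "collections")
    collection = GeneSetCollection(collection_name)
    labels: dict[str, str] = {}
    for name, ps in truth.planted.items():
        collection.add(name, f"planted {ps.direction} (effect {ps.effect_factor})",
                       truth.membership[name])
        labels[name] = f"planted_{ps.direction}"
    background = sorted(set(truth.genes) - truth.planted_genes())
    if config.n_null_sets > 0 and config.null_set_size > len(background):
        raise ValueError("null_set_size exceeds the number of non-planted genes")
    for i in range(config.n_null_sets):
        idx = rng.choice(len(background), size=config.null_set_size, replace=False)
        name = f"NULL_{i + 1:02d}"
        collection.add(name, "random background set", [background[j] for j in idx])
        labels[name] = "null"
    return collection, labels


def generate_benchmark(
    config: GeneratorConfig,
) -> tuple[
    list[InteractionRecord], GenePresenceTable, GeneSetCollection, dict[str, str], GroundTruth
]:
    """One-call generation of a full synthetic study."""
    truth = gen_universe(config)
    records, presence = gen_interactions(truth, config)
    collection, labels = gen_collections(truth, config)
    return records, presence, collection, labels, truth


def write_benchmark(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic study to disk in the pipeline's interchange formats."""
    from .io import write_gene_presence, write_gmt, write_interactions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, presence, collection, labels, truth = generate_benchmark(config)
    paths = {
        "interactions": outdir / "interactions.tsv",
        "presence": outdir / "gene_presence.tsv",
        "gmt": outdir / "gene_sets.gmt",
        "truth": outdir / "ground_truth.json",
    }
    write_interactions(records, paths["interactions"])
    write_gene_presence(presence, paths["presence"])
    write_gmt(collection, paths["gmt"])
    truth_doc = json.loads(truth.to_json())
    truth_doc["labels"] = labels
    paths["truth"].write_text(json.dumps(truth_doc, indent=1))
    return paths
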