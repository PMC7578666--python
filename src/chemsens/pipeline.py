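"""End-to-end orchestration: ingest -> validate -> filter -> dedup -> count
-> center -> enrich -> classify -> report.

A run is driven by one declarative config (YAML).  Every stage logs one
structured line with its input/output counts, all artifacts are written as
deterministic text (TSV/RNK/GMT/JSON), and a manifest records the config,
input checksums, stage counts, the centering constant and the seed, so any
number in the manifest can be recomputed from the stage artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .enrichment import (
    EnrichmentParams,
    EnrichmentReport,
    EnrichmentResult,
    plot_data,
    run_enrichment,
)
from .filters import deduplicate, filter_shared_genes, filter_taxa, subset_by_use, validate_annotations
from .io import read_gene_presence, read_gmt, read_interactions
from .records import Taxon
from .scores import center_scores, count_interactions, rank_genes, write_counts, write_rnk
from .simulate import GeneratorConfig, PlantedSet, write_benchmark


@dataclass
class PipelineConfig:
    """Declarative description of one analysis run."""

    interactions: str | None = None
    presence: str | None = None
    gene_sets: dict[str, str] = field(default_factory=dict)  # collection name -> GMT path
    outdir: str = "chemsens_run"
    taxa: tuple[str, ...] = ("Homo", "Mus", "Rattus")
    use_term: str | None = None
    metric: str = "total"
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    generator: GeneratorConfig | None = None  # demo mode: synthesize inputs first

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        enr = EnrichmentParams(**doc.pop("enrichment", {}))
        gen_doc = doc.pop("generator", None)
        gen = None
        if gen_doc is not None:
            planted = gen_doc.pop("planted_sets", None)
            if planted is not None:
                gen_doc["planted_sets"] = [PlantedSet(**p) for p in planted]
            gen = GeneratorConfig(**gen_doc)
        taxa = tuple(doc.pop("taxa", ("Homo", "Mus", "Rattus")))
        return cls(taxa=taxa, enrichment=enr, generator=gen, **doc)

    def to_dict(self) -> dict:
        # round-trip through JSON so the echo in the manifest is exactly what
        # a reloaded manifest will contain (tuples become lists, etc.)
        return json.loads(json.dumps(dataclasses.asdict(self)))


@dataclass
class RunManifest:
    """Audit record of one completed run."""

    config: dict
    input_checksums: dict[str, str]
    n_read: int
    n_after_taxa: int
    n_after_gene_filter: int
    n_after_use_subset: int
    n_after_dedup: int
    n_collapsed: int
    n_direction_conflicts: int
    n_removed_genes: int
    n_genes: int
    shift_constant: float
    collections: dict[str, dict[str, int]]  # name -> {tested, excluded}
    version: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _format_float(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return f"{x:.6g}"


def write_results_tsv(results: Sequence[EnrichmentResult], path: Path) -> None:
    """Write enrichment results mirroring the deposited schema, plus the call."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "collection of gene sets\tgene set name\tgene set size\t"
            "enrichment score\tnormalised enrichment score\t"
            "nominal p-value\tFDR q-value\tcall\n"
        )
        for r in results:
            fh.write(
                f"{r.collection}\t{r.set_name}\t{r.set_size}\t"
                f"{_format_float(r.es)}\t{_format_float(r.nes)}\t"
                f"{_format_float(r.p_nominal)}\t{_format_float(r.fdr_q)}\t{r.call}\n"
            )


def run_pipeline(config: PipelineConfig, log_lines: list[str] | None = None) -> RunManifest:
    """Execute every stage and write all artifacts under ``config.outdir``.

    Raises :class:`StageError` with the failing stage named.  Two runs with
    identical config (and inputs) produce byte-identical artifacts.
    """
    log: list[str] = log_lines if log_lines is not None else []

    def stage(name: str, **counts: int) -> None:
        log.append(json.dumps({"stage": name, **counts}, sort_keys=True))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        paths = write_benchmark(config.generator, outdir / "inputs")
        config = dataclasses.replace(
            config,
            interactions=str(paths["interactions"]),
            presence=str(paths["presence"]),
            gene_sets={"SYNTHETIC": str(paths["gmt"])},
        )
        stage("generate", n_files=len(paths))
    if not config.interactions or not config.presence or not config.gene_sets:
        raise StageError("configure", "interactions, presence and gene_sets paths are required")

    checksums = {}
    for label, p in [
        ("interactions", config.interactions),
        ("presence", config.presence),
        *[(f"gene_sets:{name}", path) for name, path in config.gene_sets.items()],
    ]:
        p = Path(p)
        if not p.exists():
            raise StageError("configure", f"input path does not exist: {p}")
        checksums[label] = _sha256(p)

    try:
        records = read_interactions(config.interactions)
    except Exception as exc:
        raise StageError("read", str(exc)) from exc
    n_read = len(records)
    stage("read", n_records=n_read)

    violations = validate_annotations(records)
    if violations:
        first = violations[0]
        raise StageError(
            "validate",
            f"{len(violations)} use-annotation violations; first: record "
            f"{first.index} ({first.reason})",
        )
    stage("validate", n_violations=0)

    try:
        taxa = frozenset(Taxon(t) for t in config.taxa)
    except ValueError as exc:
        raise StageError("filter_taxa", str(exc)) from exc
    records = filter_taxa(records, taxa)
    stage("filter_taxa", n_records=len(records))
    n_after_taxa = len(records)

    try:
        presence = read_gene_presence(config.presence)
        records, removed_genes = filter_shared_genes(records, presence)
    except Exception as exc:
        raise StageError("filter_genes", str(exc)) from exc
    stage("filter_genes", n_records=len(records), n_removed_genes=len(removed_genes))
    n_after_genes = len(records)

    if config.use_term:
        try:
            records = subset_by_use(records, config.use_term)
        except ValueError as exc:
            raise StageError("subset_use", str(exc)) from exc
    stage("subset_use", n_records=len(records))
    n_after_use = len(records)

    records, dedup_report = deduplicate(records)
    stage("dedup", n_records=len(records), n_collapsed=dedup_report.n_collapsed)

    table = count_interactions(records)
    if not table:
        raise StageError("count", "no genes left after filtering")
    write_counts(sorted(table, key=lambda r: (-r.n_total, r.gene)), outdir / "gene_counts.tsv")
    stage("count", n_genes=len(table))

    try:
        ranked = center_scores(rank_genes(table, config.metric))
    except ValueError as exc:
        raise StageError("center", str(exc)) from exc
    write_rnk(ranked, outdir / "ranked_genes.rnk")
    stage("center", n_genes=len(ranked), shift=round(ranked.shift, 6))

    collections = []
    for name, path in config.gene_sets.items():
        try:
            collections.append(read_gmt(path, collection_name=name))
        except Exception as exc:
            raise StageError("read_gene_sets", f"{name}: {exc}") from exc
    report: EnrichmentReport = run_enrichment(
        ranked, collections, config.enrichment, keep_profiles=True
    )
    stage(
        "enrich",
        n_tested=len(report.results),
        n_excluded=len(report.excluded),
    )

    per_collection: dict[str, dict[str, int]] = {}
    for coll in collections:
        tested = [r for r in report.results if r.collection == coll.collection_name]
        excl = [e for e in report.excluded if e.collection == coll.collection_name]
        per_collection[coll.collection_name] = {"tested": len(tested), "excluded": len(excl)}
        write_results_tsv(tested, outdir / f"enrichment_{coll.collection_name}.tsv")
    write_results_tsv(report.results, outdir / "enrichment_combined.tsv")
    with open(outdir / "excluded_sets.tsv", "w", encoding="utf-8") as fh:
        fh.write("collection\tgene set name\tsize after restriction\treason\n")
        for e in report.excluded:
            fh.write(f"{e.collection}\t{e.set_name}\t{e.set_size}\t{e.reason}\n")

    plots_dir = outdir / "plots"
    plots_dir.mkdir(exist_ok=True)
    for r in report.results:
        if r.call != "neither":
            bundle = plot_data(r, report.profiles[(r.collection, r.set_name)], ranked)
            name = f"{r.collection}__{r.set_name}.json".replace("/", "_")
            (plots_dir / name).write_text(json.dumps(bundle))
    stage("report", n_called=sum(r.call != "neither" for r in report.results))

    manifest = RunManifest(
        config=config.to_dict(),
        input_checksums=checksums,
        n_read=n_read,
        n_after_taxa=n_after_taxa,
        n_after_gene_filter=n_after_genes,
        n_after_use_subset=n_after_use,
        n_after_dedup=dedup_report.n_unique,
        n_collapsed=dedup_report.n_collapsed,
        n_direction_conflicts=dedup_report.n_direction_conflicts,
        n_removed_genes=len(removed_genes),
        n_genes=len(table),
        shift_constant=ranked.shift,
        collections=per_collection,
        version=__version__,
        seed=config.enrichment.seed,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return manifest


def summarize(manifest: RunManifest, results: Sequence[EnrichmentResult]) -> str:
    """Human-readable report: call counts per collection and top tables by |NES|."""
    lines = []
    lines.append(f"chemsens {manifest.version} — run summary (seed {manifest.seed})")
    lines.append(
        f"records: {manifest.n_read} read -> {manifest.n_after_taxa} after taxa filter "
        f"-> {manifest.n_after_gene_filter} after shared-genome filter "
        f"-> {manifest.n_after_dedup} unique"
    )
    lines.append(
        f"genes ranked: {manifest.n_genes}; centering constant c = "
        f"{manifest.shift_constant:.4f}"
    )
    by_coll: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_coll.setdefault(r.collection, []).append(r)
    total_called = 0
    for coll in sorted(by_coll):
        rs = by_coll[coll]
        most = sum(r.call == "most_sensitive" for r in rs)
        least = sum(r.call == "least_sensitive" for r in rs)
        total_called += most + least
        lines.append(
            f"collection {coll}: {len(rs)} sets tested, "
            f"{most} most sensitive, {least} least sensitive"
        )
    if total_called == 0:
        lines.append("no gene set met the sensitivity thresholds (zero called sets)")
    finite = [r for r in results if math.isfinite(r.nes)]
    top = sorted(finite, key=lambda r: -abs(r.nes))[:10]
    lines.append("top sets by |NES|:")
    lines.append("  rank  collection  set  size  ES  NES  p  q  call")
    for i, r in enumerate(top, 1):
        lines.append(
            f"  {i:>4}  {r.collection}  {r.set_name}  {r.set_size}  "
            f"{r.es:.4f}  {r.nes:.4f}  {r.p_nominal:.4g}  {r.fdr_q:.4g}  {r.call}"
        )
    return "\n".join(lines) + "\n"


def read_results_tsv(path: str | Path) -> list[EnrichmentResult]:
    """Read back a results TSV written by :func:`write_results_tsv`."""
    results = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("collection of gene sets"):
            raise ValueError(f"not a chemsens results table: {path}")
        for line in fh:
            if not line.strip():
                continue
            c, name, size, es, nes, p, q, call = line.rstrip("\n").split("\t")

            def num(tok: str) -> float:
                return math.nan if tok == "NA" else float(tok)

            results.append(
                EnrichmentResult(
                    collection=c,
                    set_name=name,
                    set_size=int(size),
                    es=num(es),
                    nes=num(nes),
                    p_nominal=num(p),
                    fdr_q=num(q),
                    call=call,
                )
            )
    return results
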