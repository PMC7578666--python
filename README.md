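# chemsens

Quantify the sensitivity of genes — and of whole molecular pathways — to
chemical exposures, from tables of chemical–gene interactions.

## The problem

High-throughput toxicogenomic experiments (microarray, RNA-seq) report,
for a chemical exposure in human, mouse or rat cells or tissues, which
genes significantly changed expression. Aggregated over many studies and
many chemicals (as in CTD-style chemical–gene interaction exports), the
number of distinct interactions a gene accumulates is a natural, unbiased
proxy for how *sensitive* that gene is to chemical exposures in general.
`chemsens` turns a table of such interaction records into:

1. a per-gene sensitivity table (suppressive / activating / unspecified /
   total interaction counts);
2. a centered ranked gene list suitable for signed enrichment analysis;
3. per-pathway enrichment statistics (ES, NES, nominal p, FDR q) that
   classify gene sets from Hallmark/KEGG/Reactome-style collections as
   **most sensitive** or **least sensitive** to chemical exposures.

It is aimed at computational toxicologists and risk assessors who want a
reproducible, scriptable version of this analysis, plus a synthetic-data
benchmark to validate every stage without any external download.

## The method

**Filtering.** Records are restricted to the three model taxa (Homo, Mus,
Rattus); genes not present in all three genomes are removed (a
gene-presence table is an input); chemicals carry 1–3 use-annotation terms
from an 11-term controlled vocabulary (pharmaceutical, recreational drug,
research, warfare, endobiotic, agricultural, cosmetics, environment, food
components, industrial, pollutant), which is validated and can be used to
subset (e.g. only `pollutant` chemicals). Repeated reports of the same
(study, biological model, chemical, gene) combination — key
(gene, chemical, PMID, taxon) — collapse to one record; conflicting
directions collapse to "unspecified".

**Ranking and centering.** Genes are ranked by interaction count
x₁ ≥ x₂ ≥ … ≥ x_N. All counts are positive, so the list is unsuitable for
a signed enrichment walk; a single constant c is subtracted from every
count so the positive and negative areas under the rank curve are equal:

    Σᵢ max(xᵢ − c, 0) = Σᵢ max(c − xᵢ, 0)   ⇔   c = mean(x)

**Enrichment.** For a gene set S, walk the ranked list: at a member
("hit") add |xᵢ − c|^p / Σ_{hits}|xⱼ − c|^p (default p = 1), at a
non-member subtract 1/(N − |S|). The enrichment score ES(S) is the signed
maximum deviation from zero. Significance comes from a gene-set
permutation null (random same-size subsets); NES = ES divided by the mean
|ES| of same-sign null values; the FDR q is the sign-stratified
ratio-of-tails estimator on the NES scale with a monotone (q-value)
envelope. A pathway is called most (least) sensitive iff NES ≥ 1.9
(≤ −1.9) and q ≤ 0.05, both inclusive.

## Worked example

The `demo` verb generates a synthetic study (2,000 genes, ~75,000
interaction lines with a heavy-tailed per-gene count distribution, three
planted-high and two planted-low pathways of 50 genes at effect factor 3
among 40 random null sets) and runs the full pipeline on the emitted files:

```
$ chemsens demo --outdir demo_run --seed 11
chemsens 0.1.0 — run summary (seed 11)
records: 74966 read -> 74966 after taxa filter -> 74966 after shared-genome filter -> 74966 unique
genes ranked: 1983; centering constant c = 37.8043
collection SYNTHETIC: 45 sets tested, 3 most sensitive, 2 least sensitive
top sets by |NES|:
  rank  collection  set  size  ES  NES  p  q  call
     1  SYNTHETIC  PLANTED_LOW_1  47  -0.5457  -2.5057  0.007874  0  least_sensitive
     2  SYNTHETIC  PLANTED_HIGH_2  50  0.8203  2.3420  0.001144  0  most_sensitive
     3  SYNTHETIC  PLANTED_HIGH_3  50  0.7935  2.2655  0.001144  0  most_sensitive
     4  SYNTHETIC  PLANTED_LOW_2  48  -0.4813  -2.2588  0.006897  0  least_sensitive
     5  SYNTHETIC  PLANTED_HIGH_1  50  0.6998  1.9979  0.001144  0.0002541  most_sensitive
     6  SYNTHETIC  NULL_23  48  -0.3190  -1.4971  0.03448  0.1657  neither
  ...
```

Reading the output: ~75 k synthetic interaction lines over 1,983 observed
genes give a mean of c ≈ 37.8 interactions per gene, which is the
centering constant. All five planted pathways are recovered with the
correct sign and q ≤ 0.05 and are the only called sets; the best null set
reaches only |NES| = 1.50 (q = 0.17). Artifacts written under `demo_run/`:
the generated inputs (`inputs/*.tsv`, `*.gmt`), `gene_counts.tsv`,
`ranked_genes.rnk`, `enrichment_*.tsv`, plot-bundle JSONs for called
sets, `manifest.json` and `run.log`.

Real data are analyzed the same way from a YAML config
(`chemsens run config.yaml`) pointing at an interactions TSV, a
gene-presence TSV and GMT files; `chemsens validate table.tsv` checks a
table's schema and use annotations, and `chemsens summarize rundir/`
re-renders the report of a finished run.

## Library use

```python
from chemsens import (read_interactions, deduplicate, count_interactions,
                      rank_genes, center_scores, run_enrichment,
                      read_gmt, EnrichmentParams)

records, _ = deduplicate(read_interactions("interactions.tsv"))
ranked = center_scores(rank_genes(count_interactions(records)))
report = run_enrichment(ranked, [read_gmt("hallmark.gmt", "Hallmark")],
                        EnrichmentParams(n_permutations=1000, seed=0))
for r in report.results[:5]:
    print(r.set_name, r.nes, r.fdr_q, r.call)
```

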