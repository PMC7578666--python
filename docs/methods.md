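# Methods

## Model and procedure

`chemsens` treats the number of distinct chemical–gene interactions
reported for a gene as a measure of that gene's sensitivity to chemical
exposures, and asks which predefined gene sets (pathways) are
over-represented among the most — or least — sensitive genes.

An *interaction* is one reported significant expression change of one gene
in one study (PMID), one biological model (taxon), for one chemical. The
identity key is therefore (gene, chemical, PMID, taxon); repeated lines
with that key are one interaction. Direction is not part of the key: if
collapsed lines disagree on direction the survivor is marked
"unspecified", because keeping both would double-count the interaction
while choosing either direction would invent information. How the
upstream curated data resolved such conflicts is not recorded in its
schema; collapse-to-unspecified is this package's convention. The schema
carries taxon as the only biological-model field, so taxon stands in for
the model in the key.

The pipeline stages are: read → validate use annotations → keep
Homo/Mus/Rattus → drop genes absent from any of the three genomes
(complete presence table required; a gene missing from the table is an
error, not a silent keep) → optional subset by a use term → deduplicate →
count per gene → rank → center → enrich → classify.

## Equal-area centering

With per-gene counts x₁…x_N (all positive), subtracting a constant c
makes the positive and negative deviations balance exactly when
Σ(xᵢ − c) = 0, i.e. c = mean(x). This is an identity, not a search: the
difference between the positive area Σ max(xᵢ−c, 0) and the negative area
Σ max(c−xᵢ, 0) *is* Σ(xᵢ−c). The centered list preserves the ranking
(subtraction is order-preserving) and sums to zero to floating tolerance.
A constant score vector is rejected rather than centered to all zeros —
a ranking with no variation carries no enrichment signal. Ranking ties
are broken by gene symbol ascending so results are reproducible; the
ranking metric (total, activating or suppressive counts) is a parameter
defaulting to total.

## Enrichment statistic

Walking the ranked list from most to least sensitive, the running sum
rises by |centered|^p / Σ_hits |centered|^p at set members and falls by
1/(N − N_hit) at non-members; ES is the signed extremum of largest
magnitude (ties between an equal positive and negative extremum resolve
positive; this is measure-zero for continuous scores). The profile
returns to zero after the last gene by construction. Weight exponent
p = 1 is the default (the classic weighted statistic); p = 0 gives the
plain Kolmogorov–Smirnov walk and is retained for oracle tests, where it
obeys an exact reversal antisymmetry. A full-universe set has ES = 1
(no decrements), as does a single top-ranked hit.

The null model is gene-set permutation: uniform random same-size subsets
of the ranked universe. Phenotype permutation is impossible here — the
input is a single preranked list, not an expression matrix. For
efficiency the per-permutation ES is computed in closed form from the
sorted hit positions only (between hits the walk only decreases, so the
extremum is attained immediately after or immediately before a hit);
this path is tested for exact agreement with the full profile walk. One
null array is shared by all sets of equal size, and each size's
generator substream is derived from (seed, size), so analyzing or
excluding one collection never shifts another's null.

NES = ES / mean(|same-sign null ES|), computed separately for positive
and negative ES (sign-stratified; whether the original analyses pooled
signs cannot be determined, and stratification is the convention that
keeps depletion calls symmetric with enrichment calls). A set whose null
contains no same-sign values gets NES = NaN, is flagged, and is excluded
from the FDR. The nominal p uses the add-one estimator
(1 + #{|null| ≥ |ES|}) / (1 + #null_same_sign) so finite permutations
never report zero.

FDR q for a positive NES\* is
[fraction of positive null NES ≥ NES\*] / [fraction of positive observed
NES ≥ NES\*], mirrored for negative, clipped to [0, 1], with the q-value
monotone envelope (running minimum from least toward most extreme NES, so
a more extreme set never has a larger q). Null NES values are pooled over
all tested sets, each normalized by its own null's same-sign means. Tail
comparisons count ties within 1e-9 of the observed value as at least as
extreme: at small universe sizes the ES distribution is discrete, and the
closed-form and profile paths can differ by ~1e-16 on mathematically
equal values, which would otherwise drop exact ties from the tail.

Calls use inclusive thresholds: most sensitive iff NES ≥ 1.9 and
q ≤ 0.05; least sensitive iff NES ≤ −1.9 and q ≤ 0.05. Set-size bounds
after restriction to the ranked universe default to 15–500, the common
preranked defaults; the permutation count defaults to 1,000. All of
these are configurable and echoed in the run manifest.

## Synthetic data generator

The generator emulates the structure of real curated interaction tables
so every stage is testable offline:

- **Latent rates.** λ_g = base_rate · exp(σZ − σ²/2), Z ~ N(0,1), so
  E[λ] = base_rate for any dispersion σ. Defaults: base_rate = 34
  interactions per gene (the scale implied by ~591 k interactions over
  ~17.3 k genes in real data of this kind) and σ = 1.0, which reproduces
  the qualitative heavy right tail and concave rank curve of real
  per-gene counts. Genes in a planted-high set have λ multiplied by the
  effect factor; planted-low sets are divided by it.
- **Records.** Each gene emits Poisson(λ_g) lines; each line draws a
  chemical uniformly, taxon and direction from weight vectors (defaults
  0.45/0.35/0.20 Homo/Mus/Rattus and 0.40/0.40/0.20 for
  increase/decrease/unspecified), a synthetic PMID, and the chemical's
  1–3 vocabulary use terms. Collisions on the dedup key are regenerated,
  so emitted tables are born deduplicated and give the dedup stage a
  clean baseline. A configurable holdout fraction of genes is marked
  absent from one genome to exercise the shared-genome filter.
- **Collections.** The planted sets plus 40 random null sets of size 50
  drawn from non-planted genes, GMT-serializable, with a ground-truth
  JSON sidecar.
- **Benchmark defaults** (also the recovery-test conditions): 2,000
  genes, three planted-high and two planted-low sets of 50 genes at
  effect factor 3, 1,000 permutations.

What the generator does *not* emulate: real chemical identities and their
correlated use profiles, per-chemical study multiplicity, dose–response,
tissue-level confounding, or cross-gene correlation within studies.
Passing the recovery benchmark therefore shows the statistics recover
rank-shifted sets under realistic count distributions — not that any
particular real pathway is correctly called.

On this benchmark the recovery rate over 20 seeded studies is about
99–100% of planted sets at q ≤ 0.05 with the correct sign, with ~0–2% of
threshold-passing calls being null sets (`scripts/acceptance.py`
recomputes these). Recovery of every planted set in every study is not
guaranteed: with a heavy-tailed background, a 50-gene set at effect 3
occasionally draws a genuinely weak enrichment (nominal p of a few
percent), which no correct FDR procedure should call.

## Numerical and design choices

- Interchange is UTF-8 TSV with a header (plus standard GMT and
  two-column RNK); spreadsheet workbooks are converted by an untested
  convenience helper. Direction accepts "+", ASCII "-", Unicode minus
  "−", and "1", and emits "+"/"-"/"1". Gene symbols are uppercased
  throughout so human and rodent symbol conventions denote one
  cross-species entity. Header matching is case-, whitespace- and
  order-insensitive.
- Unknown taxa are record-level errors, not silent filters: the analysis
  is defined downstream of taxon selection, so a stray taxon means a
  malformed input.
- RNK scores print with 12 significant digits so an external stable sort
  on the score column reproduces the in-memory order.
- Determinism: a single seed drives generation and enrichment;
  re-running an identical config yields byte-identical TSV artifacts.
  Results tables print floats with %.6g and NaN as "NA".
- Genes with zero observed interactions are absent from the counts table
  and the universe — the universe is defined by observed interactions,
  matching how such per-gene tables are constructed upstream.

## Known limitations

- Interaction counts are raw: no normalization for how intensively a
  chemical or gene has been studied, so literature bias propagates into
  the sensitivity metric by design.
- Gene-set permutation tests a different null than phenotype permutation;
  q-values are relative to random gene sets of equal size.
- The FDR ratio estimator is coarse when few sets are tested (the
  denominator is an observed tail fraction over the tested sets), so
  q-values from very small collections are unstable.
- Leading-edge analysis and expression-matrix GSEA are out of scope.
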