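"""Preranked gene-set enrichment with a permutation null.

The enrichment score (ES) of a gene set is the signed maximum deviation of
a running sum that walks the ranked gene list from most to least sensitive:
at a set member ("hit") the sum rises by the member's weight
``|centered score|^p`` (normalized so all hits together contribute 1), at a
non-member it falls by ``1/(N - N_hit)``.  A set concentrated among the
most chemically responsive genes drives the walk up early (positive ES);
a set concentrated among the least responsive genes drives it down
(negative ES).

Significance comes from a gene-set permutation null: random same-size
subsets of the universe.  ES values are normalized to NES by dividing by
the mean magnitude of same-sign null ES values, which makes scores
comparable across set sizes; the false discovery rate is a sign-stratified
ratio of null to observed tail fractions on the NES scale.  Pathways with
NES >= 1.9 (or <= -1.9) and FDR q <= 0.05 are called most (least)
sensitive to chemical exposures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .records import GeneSetCollection
from .scores import RankedList


@dataclass
class EnrichmentParams:
    """Tunable parameters of the enrichment procedure.

    weight_exponent
        Exponent p on |centered score| in the hit increment; p=1 is the
        classic weighted statistic, p=0 the plain Kolmogorov-Smirnov walk.
    n_permutations
        Number of random same-size gene subsets in the null (>= 10).
    seed
        Seed for the permutation generator; per-set-size substreams are
        derived from (seed, set size), so the null for one size does not
        depend on which other sizes are analyzed.
    min_set_size, max_set_size
        Bounds on set size after restriction to the ranked universe.
    nes_threshold, q_threshold
        Classification thresholds (inclusive): most sensitive iff
        NES >= nes_threshold and q <= q_threshold; least sensitive iff
        NES <= -nes_threshold and q <= q_threshold.
    """

    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    min_set_size: int = 15
    max_set_size: int = 500
    nes_threshold: float = 1.9
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")
        if self.max_set_size < self.min_set_size:
            raise ValueError("max_set_size must be >= min_set_size")
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")


@dataclass
class RunningProfile:
    """Full running-sum trace for one gene set on one ranked list."""

    values: np.ndarray
    hit_positions: np.ndarray  # 1-based rank indices of set members
    es_position: int  # 1-based rank attaining the extremum

    @property
    def es(self) -> float:
        return float(self.values[self.es_position - 1])


@dataclass
class EnrichmentResult:
    """Per-set enrichment outcome."""

    collection: str
    set_name: str
    set_size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    call: str = "neither"  # most_sensitive | least_sensitive | neither


@dataclass
class ExcludedSet:
    collection: str
    set_name: str
    set_size: int
    reason: str


@dataclass
class EnrichmentReport:
    """Everything one enrichment run produced, ordered by NES descending."""

    results: list[EnrichmentResult]
    excluded: list[ExcludedSet]
    profiles: dict[tuple[str, str], RunningProfile] = field(default_factory=dict)


def restrict_set(
    members: Iterable[str], ranked: RankedList, params: EnrichmentParams
) -> tuple[frozenset[str], str | None]:
    """Intersect a set with the ranked universe and apply size bounds.

    Returns ``(restricted members, None)`` if the set is testable, else
    ``(restricted members, reason)``.  Idempotent.
    """
    restricted = frozenset(members) & ranked.universe()
    n = len(restricted)
    if n < params.min_set_size:
        return restricted, f"too small after restriction ({n} < {params.min_set_size})"
    if n > params.max_set_size:
        return restricted, f"too large after restriction ({n} > {params.max_set_size})"
    return restricted, None


def _signed_extremum(pos: float, neg: float) -> float:
    """Pick the deviation of greatest magnitude; ties resolve positive."""
    return pos if pos >= -neg else neg


def enrichment_score(
    ranked: RankedList, members: Iterable[str], weight_exponent: float = 1.0
) -> tuple[float, RunningProfile]:
    """Compute the ES and the full running-sum profile for one gene set.

    The profile returns to 0 after the last gene by construction (all hit
    weights sum to 1 and all miss decrements sum to 1).  The ES is the
    profile value of greatest absolute magnitude, signed.
    """
    n = len(ranked)
    hit_idx = np.asarray(sorted(ranked.index_of(g) for g in members), dtype=np.intp)
    if hit_idx.size == 0:
        raise ValueError("gene set is empty after restriction to the universe")
    weights = np.abs(ranked.centered[hit_idx]) ** weight_exponent
    total = weights.sum()
    if total == 0:
        raise ValueError("all hit weights are zero; degenerate weighting")
    steps = np.full(n, 0.0)
    if hit_idx.size < n:
        steps -= 1.0 / (n - hit_idx.size)
        steps[hit_idx] = weights / total
    else:
        steps[hit_idx] = weights / total  # full-universe set: no misses
    values = np.cumsum(steps)
    pos = float(values.max())
    neg = float(values.min())
    es = _signed_extremum(pos, neg)
    es_position = int(np.flatnonzero(values == es)[0]) + 1
    profile = RunningProfile(
        values=values, hit_positions=hit_idx + 1, es_position=es_position
    )
    return es, profile


def _es_from_sorted_hits(
    abs_weights: np.ndarray, hit_idx: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for a batch of hit-index rows (each row sorted ascending).

    Between hits the walk only decreases, so the signed extremum is attained
    either immediately after a hit or immediately before one; evaluating the
    walk at those candidate points only gives the exact ES without building
    full profiles.
    """
    rows, k = hit_idx.shape
    if k == n:
        return np.ones(rows)
    w = abs_weights[hit_idx]
    totals = w.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a permutation drew a set with all-zero hit weights")
    cumw = np.cumsum(w, axis=1) / totals
    j = np.arange(k)
    miss_before = (hit_idx - j) / (n - k)  # misses strictly before each hit
    after = cumw - miss_before
    before = np.concatenate([np.zeros((rows, 1)), cumw[:, :-1]], axis=1) - miss_before
    pos = np.maximum(after.max(axis=1), 0.0)
    neg = np.minimum(before.min(axis=1), 0.0)
    return np.where(pos >= -neg, pos, neg)


def _null_rng(seed: int, set_size: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(set_size,)))


def null_distribution(
    ranked: RankedList, set_size: int, params: EnrichmentParams
) -> np.ndarray:
    """Signed ES values of ``n_permutations`` uniform random gene subsets.

    Reproducible for a given (seed, set size); one null array can be shared
    by every set of the same size.
    """
    n = len(ranked)
    if not 1 <= set_size <= n:
        raise ValueError(f"set_size must be in [1, {n}], got {set_size}")
    rng = _null_rng(params.seed, set_size)
    abs_weights = np.abs(ranked.centered) ** params.weight_exponent
    draws = np.empty((params.n_permutations, set_size), dtype=np.intp)
    for i in range(params.n_permutations):
        draws[i] = rng.choice(n, size=set_size, replace=False)
    draws.sort(axis=1)
    return _es_from_sorted_hits(abs_weights, draws, n)


def normalize_es(es: float, null: np.ndarray) -> float:
    """NES = ES divided by the mean magnitude of same-sign null ES values.

    Returns NaN when the null contains no same-sign values (the set is then
    flagged and excluded from FDR).
    """
    same_sign = null[null > 0] if es >= 0 else null[null < 0]
    if same_sign.size == 0:
        return math.nan
    return float(es / np.abs(same_sign).mean())


#: Tolerance for tail comparisons: null values tied with the observed value
#: up to accumulated rounding must count as at least as extreme, or discrete
#: ES ties (common at small universe sizes) would be dropped by chance.
_TIE_TOL = 1e-9


def nominal_p(es: float, null: np.ndarray) -> float:
    """Add-one tail probability of |ES| under the same-sign null."""
    same_sign = null[null > 0] if es >= 0 else null[null < 0]
    if same_sign.size == 0:
        return math.nan
    extreme = int(np.sum(np.abs(same_sign) >= abs(es) - _TIE_TOL))
    return (1 + extreme) / (1 + same_sign.size)


def fdr_q(observed_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Sign-stratified ratio-of-tails FDR on the NES scale.

    For a positive NES*, q is the fraction of positive null NES >= NES*
    divided by the fraction of positive observed NES >= NES* (mirrored for
    negative), clipped to [0, 1] and made monotone non-increasing toward
    more extreme NES.  NaN observations get NaN q.
    """
    observed_nes = np.asarray(observed_nes, dtype=float)
    q = np.full(observed_nes.shape, np.nan)
    finite = np.isfinite(observed_nes)
    for sign in (+1, -1):
        if sign > 0:
            obs_mask = finite & (observed_nes >= 0)
            null_pool = null_nes[np.isfinite(null_nes) & (null_nes >= 0)]
        else:
            obs_mask = finite & (observed_nes < 0)
            null_pool = null_nes[np.isfinite(null_nes) & (null_nes < 0)]
        obs = observed_nes[obs_mask]
        if obs.size == 0:
            continue
        raw = np.empty(obs.size)
        for i, v in enumerate(obs):
            if sign > 0:
                num = np.mean(null_pool >= v - _TIE_TOL) if null_pool.size else 0.0
                den = np.mean(obs >= v - _TIE_TOL)
            else:
                num = np.mean(null_pool <= v + _TIE_TOL) if null_pool.size else 0.0
                den = np.mean(obs <= v + _TIE_TOL)
            raw[i] = min(1.0, num / den) if den > 0 else 0.0
        # monotone: a more extreme NES never has a larger q, so accumulate the
        # running minimum from least to most extreme (BH-style)
        order = np.argsort(sign * obs)  # least extreme first
        raw[order] = np.minimum.accumulate(raw[order])
        q[obs_mask] = raw
    return q


def classify_sensitivity(
    results: Sequence[EnrichmentResult], params: EnrichmentParams
) -> list[EnrichmentResult]:
    """Fill the most/least-sensitive call from the NES and q thresholds (inclusive)."""
    for r in results:
        if not (math.isfinite(r.nes) and math.isfinite(r.fdr_q)):
            r.call = "neither"
        elif r.nes >= params.nes_threshold and r.fdr_q <= params.q_threshold:
            r.call = "most_sensitive"
        elif r.nes <= -params.nes_threshold and r.fdr_q <= params.q_threshold:
            r.call = "least_sensitive"
        else:
            r.call = "neither"
    return list(results)


def run_enrichment(
    ranked: RankedList,
    collections: Sequence[GeneSetCollection],
    params: EnrichmentParams,
    keep_profiles: bool = False,
) -> EnrichmentReport:
    """Enrich every set of every collection against one ranked list.

    Null ES arrays are computed once per distinct restricted set size and
    shared; null NES values are pooled across all tested sets for the FDR.
    Results are sorted by NES descending; excluded sets are reported with
    their reasons.  Deterministic for fixed (inputs, params, seed).
    """
    if len(ranked) == 0:
        raise ValueError("empty ranked universe")
    if not collections:
        raise ValueError("no gene-set collections supplied")

    tested: list[tuple[str, str, frozenset[str]]] = []
    excluded: list[ExcludedSet] = []
    for coll in collections:
        for name, (_desc, members) in coll.sets.items():
            restricted, reason = restrict_set(members, ranked, params)
            if reason is None:
                tested.append((coll.collection_name, name, restricted))
            else:
                excluded.append(
                    ExcludedSet(coll.collection_name, name, len(restricted), reason)
                )

    nulls: dict[int, np.ndarray] = {}
    for _, _, members in tested:
        size = len(members)
        if size not in nulls:
            nulls[size] = null_distribution(ranked, size, params)

    results: list[EnrichmentResult] = []
    profiles: dict[tuple[str, str], RunningProfile] = {}
    null_nes_pool: list[np.ndarray] = []
    for coll_name, set_name, members in tested:
        es, profile = enrichment_score(ranked, members, params.weight_exponent)
        null = nulls[len(members)]
        nes = normalize_es(es, null)
        p = nominal_p(es, null)
        results.append(
            EnrichmentResult(
                collection=coll_name,
                set_name=set_name,
                set_size=len(members),
                es=es,
                nes=nes,
                p_nominal=p,
                fdr_q=math.nan,
            )
        )
        if keep_profiles:
            profiles[(coll_name, set_name)] = profile
        # each tested set contributes its null, normalized the same way
        pos = null[null > 0]
        neg = null[null < 0]
        normed = np.concatenate(
            [
                pos / np.abs(pos).mean() if pos.size else pos,
                neg / np.abs(neg).mean() if neg.size else neg,
            ]
        )
        null_nes_pool.append(normed)

    if results:
        observed = np.array([r.nes for r in results])
        qs = fdr_q(observed, np.concatenate(null_nes_pool))
        for r, q in zip(results, qs):
            r.fdr_q = float(q)
        classify_sensitivity(results, params)

    results.sort(key=lambda r: (-(r.nes if math.isfinite(r.nes) else -math.inf), r.set_name))
    return EnrichmentReport(results=results, excluded=excluded, profiles=profiles)


def plot_data(
    result: EnrichmentResult, profile: RunningProfile, ranked: RankedList
) -> dict:
    """Plot-ready bundle for one set: running score, hit ticks, score bars.

    All series are index-aligned to ranks 1..N; the bar series is the
    centered score vector, which sums to zero by the equal-area centering.
    """
    return {
        "collection": result.collection,
        "set_name": result.set_name,
        "es": result.es,
        "nes": result.nes,
        "es_position": profile.es_position,
        "running_score": [float(v) for v in profile.values],
        "hit_positions": [int(h) for h in profile.hit_positions],
        "centered_scores": [float(v) for v in ranked.centered],
        "genes": list(ranked.genes),
    }
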