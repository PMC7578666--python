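"""Running-sum enrichment score, permutation null, NES, FDR and calls."""

import itertools
import math

import numpy as np
import pytest

from chemsens import (
    EnrichmentParams,
    EnrichmentResult,
    GeneSetCollection,
    RankedList,
    classify_sensitivity,
    enrichment_score,
    fdr_q,
    nominal_p,
    normalize_es,
    null_distribution,
    plot_data,
    restrict_set,
    run_enrichment,
)
from chemsens.enrichment import _es_from_sorted_hits


def make_ranked(scores, genes=None):
    scores = np.asarray(scores, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(len(scores))]
    centered = scores - scores.mean()
    return RankedList(genes=list(genes), raw=scores, centered=centered, shift=float(scores.mean()))


def walk_oracle(centered, hit_mask, p):
    """Straight-line re-implementation of the running sum, kept independent."""
    centered = np.asarray(centered, float)
    n = len(centered)
    n_hit = int(hit_mask.sum())
    denom = sum(abs(centered[i]) ** p for i in range(n) if hit_mask[i])
    value, best = 0.0, 0.0
    for i in range(n):
        if hit_mask[i]:
            value += abs(centered[i]) ** p / denom
        else:
            value -= 1.0 / (n - n_hit)
        if abs(value) > abs(best) or (abs(value) == abs(best) and value > best):
            best = value
    return best


@pytest.fixture
def ranked10():
    return make_ranked([30, 21, 13, 8, 5, 3, 2, 1, 1, 0])


class TestRestrictSet:
    def test_intersection_kept_when_large_enough(self, ranked10):
        params = EnrichmentParams(min_set_size=3)
        members = ["G000", "G001", "G002", "G003", "NOT_IN_UNIVERSE"]
        restricted, reason = restrict_set(members, ranked10, params)
        assert reason is None and len(restricted) == 4

    def test_too_small_after_restriction_excluded(self, ranked10):
        params = EnrichmentParams(min_set_size=5)
        restricted, reason = restrict_set(["G000", "G001", "X1", "X2", "X3"], ranked10, params)
        assert len(restricted) == 2
        assert "too small" in reason

    def test_too_large_excluded(self, ranked10):
        params = EnrichmentParams(min_set_size=1, max_set_size=4)
        _, reason = restrict_set([f"G{i:03d}" for i in range(10)], ranked10, params)
        assert "too large" in reason

    def test_idempotent(self, ranked10):
        params = EnrichmentParams(min_set_size=2)
        first, reason = restrict_set(["G000", "G005", "ABSENT"], ranked10, params)
        assert reason is None
        second, _ = restrict_set(first, ranked10, params)
        assert second == first


class TestEnrichmentScore:
    def test_single_top_gene_gives_full_deviation(self):
        ranked = make_ranked([9, 1, 1, 1])
        es, profile = enrichment_score(ranked, ["G000"], 1.0)
        assert es == 1.0
        assert profile.es_position == 1

    def test_full_universe_set_gives_one(self, ranked10):
        es, _ = enrichment_score(ranked10, ranked10.genes, 1.0)
        assert es == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.0, 1.0, 2.0])
    def test_matches_straight_line_walk_on_small_fixture(self, p):
        ranked = make_ranked([13, 9, 6, 4, 2, 1, 1, 0])
        members = ["G001", "G004", "G006"]
        hit_mask = np.array([g in members for g in ranked.genes])
        es, _ = enrichment_score(ranked, members, p)
        assert es == pytest.approx(walk_oracle(ranked.centered, hit_mask, p), abs=1e-12)

    def test_bottom_loaded_set_is_negative(self, ranked10):
        es, _ = enrichment_score(ranked10, ["G007", "G008", "G009"], 1.0)
        assert es < 0

    def test_profile_returns_to_zero(self, ranked10):
        _, profile = enrichment_score(ranked10, ["G002", "G005"], 1.0)
        assert abs(profile.values[-1]) < 1e-9
        assert profile.es_position == int(np.argmax(np.abs(profile.values))) + 1

    def test_empty_set_rejected(self, ranked10):
        with pytest.raises(ValueError):
            enrichment_score(ranked10, [], 1.0)

    def test_all_zero_hit_weights_rejected(self):
        ranked = make_ranked([4, 2, 0, 0])  # centered: 2.5, .5, -1.5, -1.5
        ranked = RankedList(
            genes=ranked.genes,
            raw=ranked.raw,
            centered=np.array([2.0, 1.0, 0.0, -3.0]),
            shift=0.0,
        )
        with pytest.raises(ValueError, match="zero"):
            enrichment_score(ranked, ["G002"], 1.0)

    def test_reversal_antisymmetry_unweighted(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 4, 40)
        scores -= scores.mean()
        ranked = make_ranked(scores)
        flipped = RankedList(
            genes=list(reversed(ranked.genes)),
            raw=ranked.raw[::-1].copy(),
            centered=-ranked.centered[::-1].copy(),
            shift=0.0,
        )
        for trial in range(10):
            members = rng.choice(ranked.genes, size=6, replace=False)
            es_fwd, _ = enrichment_score(ranked, members, 0.0)
            es_rev, _ = enrichment_score(flipped, members, 0.0)
            assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_batch_formula_agrees_with_profile(self):
        rng = np.random.default_rng(11)
        scores = np.sort(rng.lognormal(2, 1, 80))[::-1]
        ranked = make_ranked(scores)
        abs_w = np.abs(ranked.centered)
        for k in (1, 5, 20, 79, 80):
            draws = np.sort(
                np.array([rng.choice(80, size=k, replace=False) for _ in range(30)]), axis=1
            )
            batch = _es_from_sorted_hits(abs_w, draws, 80)
            for row, es_b in zip(draws, batch):
                es_p, _ = enrichment_score(ranked, [ranked.genes[i] for i in row], 1.0)
                assert es_b == pytest.approx(es_p, abs=1e-10)


class TestNullDistribution:
    def test_seed_reproducibility(self, ranked10):
        params = EnrichmentParams(n_permutations=50, seed=9)
        a = null_distribution(ranked10, 3, params)
        b = null_distribution(ranked10, 3, params)
        assert np.array_equal(a, b)

    def test_substream_independent_of_other_sizes(self, ranked10):
        params = EnrichmentParams(n_permutations=50, seed=9)
        a = null_distribution(ranked10, 3, params)
        null_distribution(ranked10, 5, params)
        b = null_distribution(ranked10, 3, params)
        assert np.array_equal(a, b)

    def test_full_size_sets_have_unit_es(self, ranked10):
        params = EnrichmentParams(n_permutations=20, seed=1)
        null = null_distribution(ranked10, len(ranked10), params)
        assert np.all(null == 1.0)

    def test_mean_matches_exhaustive_enumeration(self):
        ranked = make_ranked([8, 5, 3, 2, 1, 0])
        exhaustive = [
            enrichment_score(ranked, [ranked.genes[i], ranked.genes[j]], 1.0)[0]
            for i, j in itertools.combinations(range(6), 2)
        ]
        params = EnrichmentParams(n_permutations=2000, seed=17)
        null = null_distribution(ranked, 2, params)
        se = np.std(exhaustive, ddof=1) / math.sqrt(params.n_permutations)
        assert abs(null.mean() - np.mean(exhaustive)) <= 3 * se

    def test_all_values_within_unit_interval(self, ranked10):
        params = EnrichmentParams(n_permutations=500, seed=2)
        for size in (1, 3, 7):
            null = null_distribution(ranked10, size, params)
            assert np.all(null >= -1) and np.all(null <= 1)


class TestNormalizeAndP:
    def test_nes_arithmetic(self):
        null = np.array([0.3, 0.3, -0.2, -0.4])
        assert normalize_es(0.6, null) == pytest.approx(2.0)

    def test_es_equal_to_null_mean_gives_unit_nes(self):
        null = np.array([0.25, 0.35, -0.5])
        assert normalize_es(0.3, null) == pytest.approx(1.0)

    def test_no_same_sign_null_flags_missing(self):
        assert math.isnan(normalize_es(0.5, np.array([-0.1, -0.2])))
        assert math.isnan(nominal_p(0.5, np.array([-0.1, -0.2])))

    def test_nes_matches_recomputation_on_planted_fixture(self, small_benchmark):
        from chemsens import center_scores, count_interactions, deduplicate, rank_genes

        records, _ = deduplicate(small_benchmark["records"])
        ranked = center_scores(rank_genes(count_interactions(records)))
        params = EnrichmentParams(n_permutations=200, min_set_size=5, seed=4)
        members, reason = restrict_set(
            small_benchmark["collection"].sets["PLANTED_HIGH_A"][1], ranked, params
        )
        assert reason is None
        es, _ = enrichment_score(ranked, members, params.weight_exponent)
        null = null_distribution(ranked, len(members), params)
        nes = normalize_es(es, null)
        same_sign = null[null > 0] if es >= 0 else null[null < 0]
        assert nes == pytest.approx(es / np.mean(np.abs(same_sign)))

    def test_p_extreme_es_hits_add_one_floor(self):
        null = np.array([0.1, 0.2, 0.3, -0.5])
        assert nominal_p(0.9, null) == pytest.approx(1 / 4)  # 3 positive nulls

    def test_p_at_null_median_is_about_half(self):
        rng = np.random.default_rng(21)
        null = np.abs(rng.normal(0, 0.2, 999))
        med = float(np.median(null))
        assert nominal_p(med, null) == pytest.approx(0.5, abs=0.01)

    def test_p_monotone_in_magnitude(self):
        rng = np.random.default_rng(22)
        null = np.abs(rng.normal(0, 0.2, 400))
        ps = [nominal_p(v, null) for v in np.linspace(0.01, 0.9, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestFdr:
    def test_no_null_as_extreme_gives_zero(self):
        q = fdr_q(np.array([2.5]), np.array([0.5, 1.0, -0.7]))
        assert q[0] == 0.0

    def test_matches_two_pass_counting_oracle(self):
        rng = np.random.default_rng(31)
        observed = np.concatenate([rng.normal(1, 0.5, 12), rng.normal(-1, 0.5, 9)])
        null = rng.normal(0, 1, 500)
        q = fdr_q(observed, null)
        pos_null = null[null >= 0]
        pos_obs = observed[observed >= 0]
        raw = {}
        for v in pos_obs:
            num = np.sum(pos_null >= v) / pos_null.size
            den = np.sum(pos_obs >= v) / pos_obs.size
            raw[v] = min(1.0, num / den)
        for v in pos_obs:
            # monotone envelope: min of the raw ratio over thresholds that
            # are no more extreme (reject-at-least-as-much), q-value style
            expected = min(raw[u] for u in pos_obs if u <= v)
            i = int(np.flatnonzero(observed == v)[0])
            assert q[i] == pytest.approx(expected)

    def test_clipped_to_unit_interval(self):
        rng = np.random.default_rng(32)
        observed = rng.normal(0, 1, 40)
        null = rng.normal(0, 2, 1000)
        q = fdr_q(observed, null)
        assert np.all((q >= 0) & (q <= 1))

    def test_monotone_toward_extreme_nes(self):
        rng = np.random.default_rng(33)
        observed = rng.normal(0.8, 0.6, 30)
        null = rng.normal(0, 1, 800)
        q = fdr_q(observed, null)
        pos = observed >= 0
        order = np.argsort(observed[pos])
        assert np.all(np.diff(q[pos][order]) <= 1e-12)


class TestClassification:
    def result(self, nes, q):
        return EnrichmentResult("C", "S", 30, math.copysign(0.5, nes), nes, 0.01, q)

    @pytest.mark.parametrize(
        "nes,q,expected",
        [
            (2.1, 0.01, "most_sensitive"),
            (1.95, 0.2, "neither"),
            (1.9, 0.05, "most_sensitive"),  # inclusive boundary
            (-1.9, 0.05, "least_sensitive"),  # inclusive boundary
            (-2.4, 0.051, "neither"),
            (1.2, 0.001, "neither"),
            (float("nan"), 0.01, "neither"),
        ],
    )
    def test_threshold_semantics(self, nes, q, expected):
        params = EnrichmentParams()
        (out,) = classify_sensitivity([self.result(nes, q)], params)
        assert out.call == expected


class TestRunEnrichment:
    def test_top_loaded_set_positive_nes(self, ranked10):
        coll = GeneSetCollection("C")
        coll.add("TOP", "", ["G000", "G001", "G002"])
        params = EnrichmentParams(n_permutations=100, min_set_size=2, seed=5)
        report = run_enrichment(ranked10, [coll], params)
        (r,) = report.results
        assert r.nes > 0 and r.es > 0

    def test_deterministic_for_fixed_seed(self, small_benchmark):
        from chemsens import center_scores, count_interactions, deduplicate, rank_genes

        records, _ = deduplicate(small_benchmark["records"])
        ranked = center_scores(rank_genes(count_interactions(records)))
        params = EnrichmentParams(n_permutations=100, min_set_size=5, seed=6)
        a = run_enrichment(ranked, [small_benchmark["collection"]], params)
        b = run_enrichment(ranked, [small_benchmark["collection"]], params)
        assert [(r.set_name, r.es, r.nes, r.p_nominal, r.fdr_q, r.call) for r in a.results] == [
            (r.set_name, r.es, r.nes, r.p_nominal, r.fdr_q, r.call) for r in b.results
        ]

    def test_results_sorted_by_nes_descending(self, small_benchmark):
        from chemsens import center_scores, count_interactions, deduplicate, rank_genes

        records, _ = deduplicate(small_benchmark["records"])
        ranked = center_scores(rank_genes(count_interactions(records)))
        params = EnrichmentParams(n_permutations=100, min_set_size=5, seed=6)
        report = run_enrichment(ranked, [small_benchmark["collection"]], params)
        nes = [r.nes for r in report.results if math.isfinite(r.nes)]
        assert nes == sorted(nes, reverse=True)

    def test_undersized_sets_reported_excluded(self, ranked10):
        coll = GeneSetCollection("C")
        coll.add("TINY", "", ["G000"])
        coll.add("OK", "", ["G000", "G001", "G002"])
        params = EnrichmentParams(n_permutations=50, min_set_size=2, seed=5)
        report = run_enrichment(ranked10, [coll], params)
        assert [e.set_name for e in report.excluded] == ["TINY"]
        assert [r.set_name for r in report.results] == ["OK"]

    def test_empty_universe_rejected(self):
        ranked = RankedList(genes=[], raw=np.array([]), centered=np.array([]), shift=0.0)
        with pytest.raises(ValueError):
            run_enrichment(ranked, [GeneSetCollection("C", {"S": ("", frozenset({"A"}))})],
                           EnrichmentParams(n_permutations=10))


class TestPlotData:
    def test_series_aligned_to_ranks(self, ranked10):
        params = EnrichmentParams(n_permutations=50, min_set_size=2, seed=5)
        coll = GeneSetCollection("C")
        coll.add("S", "", ["G000", "G003", "G006"])
        report = run_enrichment(ranked10, [coll], params, keep_profiles=True)
        (r,) = report.results
        bundle = plot_data(r, report.profiles[("C", "S")], ranked10)
        n = len(ranked10)
        assert len(bundle["running_score"]) == n
        assert len(bundle["centered_scores"]) == n
        assert bundle["hit_positions"] == [1, 4, 7]
        extremum = bundle["running_score"][bundle["es_position"] - 1]
        assert extremum == pytest.approx(r.es)
        assert abs(extremum) == pytest.approx(max(abs(v) for v in bundle["running_score"]))

    def test_bar_series_sums_to_zero(self, ranked10):
        params = EnrichmentParams(n_permutations=50, min_set_size=2, seed=5)
        coll = GeneSetCollection("C")
        coll.add("S", "", ["G001", "G002"])
        report = run_enrichment(ranked10, [coll], params, keep_profiles=True)
        bundle = plot_data(report.results[0], report.profiles[("C", "S")], ranked10)
        assert sum(bundle["centered_scores"]) == pytest.approx(0, abs=1e-9)


class TestAgainstIndependentImplementation:
    def test_es_agrees_with_gseapy_prerank(self):
        """Cross-check the weighted running-sum ES against gseapy on one fixture."""
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        rng = np.random.default_rng(5)
        genes = [f"G{i:03d}" for i in range(60)]
        scores = np.sort(rng.normal(0, 5, 60))[::-1]
        scores -= scores.mean()
        ranked = RankedList(genes=genes, raw=scores.copy(), centered=scores, shift=0.0)
        sets = {"S1": genes[2:20:3] + genes[40:44], "S2": genes[45:58]}
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": scores}),
            gene_sets={k: list(v) for k, v in sets.items()},
            min_size=3,
            max_size=500,
            permutation_num=10,
            seed=7,
            outdir=None,
            no_plot=True,
            weight=1.0,
        )
        theirs = dict(zip(res.res2d["Term"], res.res2d["ES"]))
        for name, members in sets.items():
            ours, _ = enrichment_score(ranked, members, 1.0)
            assert ours == pytest.approx(float(theirs[name]), abs=1e-9)
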