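"""Contingency construction, Fisher test, FDR, and Lancaster combination."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import gammaincc
from scipy.stats import chi2

from mirpath.errors import ValidationError
from mirpath.enrichment import (
    ContingencyTable,
    DegeneratePathwayError,
    MiRNAScore,
    NullModel,
    PairResult,
    build_contingency,
    combine_lancaster,
    enrichment_analysis,
    estimate_null,
    fdr_adjust,
    fisher_one_tailed,
    fisher_one_tailed_many,
    lancaster_transform,
    rank_and_select,
)
from mirpath.gene_sets import PathwayRecord, RelevanceClass
from mirpath.targets import TargetMap, build_universe
from mirpath.synthetic import SyntheticScenario, simulate


def pathway(pid, genes, label="A"):
    return PathwayRecord(
        pathway_id=pid, name=pid, core_genes=frozenset(genes),
        relevance=RelevanceClass.from_label(label),
    )


def exact_upper_tail(np_plus, np_minus, nm_plus, nm_minus):
    """Exact hypergeometric upper tail by integer combinatorial summation."""
    N = nm_plus + nm_minus
    K = np_plus + np_minus
    n = nm_plus
    hi = min(n, K)
    num = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(np_plus, hi + 1)
    )
    return float(Fraction(num, math.comb(N, n)))


class TestContingency:
    def test_pathway_restricted_to_universe(self):
        # G99 is in the pathway but never annotated as anyone's target
        tmap = TargetMap(mode="VMT", targets={
            "m1": frozenset({"G1", "G2"}),
            "m2": frozenset(f"G{i}" for i in range(1, 11)),
        })
        universe = build_universe(tmap)
        assert universe == frozenset(f"G{i}" for i in range(1, 11))
        pw = pathway("P1", {"G1", "G3", "G99"})
        t = build_contingency("m1", pw, tmap, universe)
        assert (t.np_plus, t.np_minus, t.nm_plus, t.nm_minus) == (1, 1, 2, 8)

    def test_disjoint_targets_give_zero_overlap(self):
        tmap = TargetMap(mode="VMT", targets={
            "m1": frozenset({"G1"}), "m2": frozenset({"G2", "G3"})})
        t = build_contingency(
            "m1", pathway("P1", {"G2", "G3"}), tmap, build_universe(tmap)
        )
        assert t.np_plus == 0

    def test_full_coverage_gives_zero_np_minus(self):
        tmap = TargetMap(mode="VMT", targets={
            "m1": frozenset({"G1", "G2"}), "m2": frozenset({"G3"})})
        t = build_contingency(
            "m1", pathway("P1", {"G1", "G2"}), tmap, build_universe(tmap)
        )
        assert t.np_minus == 0

    def test_degenerate_pathway_flagged(self):
        tmap = TargetMap(mode="VMT", targets={"m1": frozenset({"G1"})})
        with pytest.raises(DegeneratePathwayError):
            build_contingency(
                "m1", pathway("P1", {"G98", "G99"}), tmap,
                build_universe(tmap),
            )

    @pytest.mark.parametrize(
        "counts", [(-1, 1, 2, 8), (3, 1, 2, 8), (5, 9, 5, 8)]
    )
    def test_invariant_violations_rejected(self, counts):
        with pytest.raises(ValidationError):
            ContingencyTable(*counts)


class TestFisher:
    def test_zero_overlap_gives_p_one(self):
        assert fisher_one_tailed(ContingencyTable(0, 4, 5, 15)) == 1.0

    def test_exact_combinatorial_example(self):
        # N=20, K=4, n=5: p = sum_{k=2..4} C(4,k) C(16,5-k) / C(20,5)
        t = ContingencyTable(2, 2, 5, 15)
        expected = exact_upper_tail(2, 2, 5, 15)
        assert fisher_one_tailed(t) == pytest.approx(expected, abs=1e-12)

    @given(
        st.integers(1, 40), st.integers(0, 40), st.integers(0, 40),
        st.integers(0, 40),
    )
    def test_matches_exact_summation_on_small_tables(self, N, K, n, k):
        K, n = min(K, N), min(n, N)
        k = min(k, K, n)
        if (K - k) > (N - n):  # np_minus <= nm_minus must hold
            k = K - (N - n)
        t = ContingencyTable(k, K - k, n, N - n)
        assert fisher_one_tailed(t) == pytest.approx(
            exact_upper_tail(k, K - k, n, N - n), abs=1e-12
        )

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        tables = []
        for _ in range(200):
            N = int(rng.integers(2, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, K - (N - n)), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            tables.append((k, K - k, n, N - n))
        batch = fisher_one_tailed_many(
            np.array([t[0] for t in tables]),
            np.array([t[2] + t[3] for t in tables]),
            np.array([t[0] + t[1] for t in tables]),
            np.array([t[2] for t in tables]),
        )
        scalar = np.array(
            [fisher_one_tailed(ContingencyTable(*t)) for t in tables]
        )
        np.testing.assert_allclose(batch, scalar, rtol=0, atol=1e-15)


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_array_equal(fdr_adjust([0.01]), [0.01])

    def test_stepup_by_hand(self):
        # min over i of p_(i) * m / i with step-up: all become 0.04
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_empty_input(self):
        assert fdr_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.0, 0.5])

    @given(st.lists(st.floats(1e-10, 1.0), min_size=2, max_size=60))
    def test_rank_order_preserved(self, ps):
        adj = fdr_adjust(ps)
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 80)))
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)

    def test_grouped_scope_equals_separate_calls(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        out = fdr_adjust(p, groups=groups)
        for g in "abc":
            mask = groups == g
            np.testing.assert_array_equal(out[mask], fdr_adjust(p[mask]))


class TestLancasterTransform:
    def test_weight_two_is_fisher_transform(self):
        for p in (0.05, 0.3, 0.9):
            assert lancaster_transform(p, 2.0) == pytest.approx(
                -2.0 * math.log(p), abs=1e-10
            )
        assert lancaster_transform(0.05, 2.0) == pytest.approx(5.9915, abs=1e-4)

    @pytest.mark.parametrize("w", [0.5, 1.0, 2.0, 7.3])
    def test_p_one_maps_to_zero(self, w):
        assert lancaster_transform(1.0, w) == 0.0

    def test_fractional_df_matches_bisection_oracle(self):
        # median of Gamma(0.25, 2) by root-finding on the regularized
        # upper incomplete gamma (survival function)
        def oracle(p, w, lo=0.0, hi=1e4):
            for _ in range(200):
                mid = (lo + hi) / 2
                if gammaincc(w / 2, mid / 2) > p:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        for p, w in [(0.5, 0.5), (0.1, 0.5), (0.7, 1.5)]:
            assert lancaster_transform(p, w) == pytest.approx(
                oracle(p, w), abs=1e-8
            )

    def test_p_zero_is_capped_not_infinite(self):
        assert math.isfinite(lancaster_transform(0.0, 2.0))

    def test_bad_weight_rejected(self):
        with pytest.raises(ValidationError):
            lancaster_transform(0.5, 0.0)


def make_pairs(mirna, ps):
    table = ContingencyTable(1, 1, 2, 8)
    return [
        PairResult(mirna=mirna, pathway_id=f"P{i}", p_raw=p, p_adj=p,
                   table=table)
        for i, p in enumerate(ps)
    ]


class TestCombine:
    def test_all_weights_two_equals_fisher_combined(self):
        ps = [0.02, 0.4, 0.77, 0.15]
        weights = {f"P{i}": 2.0 for i in range(4)}
        null = NullModel(kind="independent", df_effective=8.0)
        score = combine_lancaster(make_pairs("m", ps), weights, null)
        T_fisher = -2.0 * sum(math.log(p) for p in ps)
        assert score.lancaster_T == pytest.approx(T_fisher, abs=1e-10)
        assert score.p_combined == pytest.approx(
            float(chi2.sf(T_fisher, df=8)), abs=1e-10
        )

    @pytest.mark.parametrize("w", [0.5, 1.0, 2.0])
    def test_single_pathway_round_trip(self, w):
        # quantile then tail of the same distribution returns p itself
        null = NullModel(kind="independent", df_effective=w)
        score = combine_lancaster(
            make_pairs("m", [0.037]), {"P0": w}, null
        )
        assert score.p_combined == pytest.approx(0.037, abs=1e-9)

    def test_monte_carlo_oracle_mixed_weights(self):
        # k=3, p=(0.01, 0.5, 0.9), w=(2, 1, 0.5), independent null
        ps, ws = [0.01, 0.5, 0.9], [2.0, 1.0, 0.5]
        weights = {f"P{i}": w for i, w in enumerate(ws)}
        null = NullModel(kind="independent", df_effective=sum(ws))
        score = combine_lancaster(make_pairs("m", ps), weights, null)
        rng = np.random.default_rng(12345)
        n = 10_000_000
        total = np.zeros(n)
        for w in ws:
            total += rng.gamma(shape=w / 2.0, scale=2.0, size=n)
        p_mc = float(np.mean(total >= score.lancaster_T))
        se = math.sqrt(p_mc * (1 - p_mc) / n)
        assert abs(score.p_combined - p_mc) <= 3 * se

    def test_weight_pathway_mismatch_rejected(self):
        null = NullModel(kind="independent", df_effective=2.0)
        with pytest.raises(ValidationError):
            combine_lancaster(
                make_pairs("m", [0.1]), {"OTHER": 2.0}, null
            )

    def test_permutation_null_counts_exceedances(self):
        perm = np.array([1.0, 2.0, 3.0, 4.0] * 25)
        null = NullModel(
            kind="permutation", n_permutations=100, perm_T=perm
        )
        score = combine_lancaster(
            make_pairs("m", [0.05]), {"P0": 2.0}, null
        )
        ge = int(np.sum(perm >= score.lancaster_T))
        assert score.p_combined == pytest.approx((1 + ge) / 101)


class TestRankAndSelect:
    def test_strict_threshold(self):
        scores = [
            MiRNAScore("a", 5.0, 4.0, 0.005),
            MiRNAScore("b", 4.0, 4.0, 0.01),
            MiRNAScore("c", 1.0, 4.0, 0.5),
        ]
        ranked = rank_and_select(scores, alpha=0.01)
        assert [s.mirna for s in ranked if s.selected] == ["a"]
        assert [s.rank for s in ranked] == [1, 2, 3]

    def test_empty_input(self):
        assert rank_and_select([]) == []

    def test_tie_break_by_T_then_name(self):
        scores = [
            MiRNAScore("z", 3.0, 4.0, 0.2),
            MiRNAScore("a", 3.0, 4.0, 0.2),
            MiRNAScore("b", 9.0, 4.0, 0.2),
        ]
        ranked = rank_and_select(scores)
        assert [s.mirna for s in ranked] == ["b", "a", "z"]


class TestEstimateNull:
    def _disjoint_data(self, seed=5):
        sc = SyntheticScenario(
            n_genes=4000, n_pathways=10, pathway_size_range=(100, 100),
            n_mirnas=100, target_size_range=(400, 400),
            tf_edge_density=0.0, seed=seed,
        )
        ds = simulate(sc)
        return ds.pathways, ds.vmt, build_universe(ds.vmt)

    def test_independence_sanity(self):
        # disjoint equal-size pathways, uniform targets, raw combining:
        # df_eff ~ sum(w); scale sits slightly below 1 because discrete
        # hypergeometric p-values are stochastically larger than uniform
        pathways, tmap, universe = self._disjoint_data()
        null = estimate_null(
            pathways, tmap, universe, n_permutations=2000, seed=5,
            combine_on="raw",
        )
        sw = sum(p.weight for p in pathways)
        assert null.kind == "moment_matched"
        assert abs(null.df_effective - sw) <= 0.15 * sw
        assert 0.7 < null.scale < 1.05

    def test_duplicated_pathway_shrinks_effective_df(self):
        pathways, tmap, universe = self._disjoint_data(seed=6)
        twin = [pathways[0], pathway("DUP", pathways[0].core_genes, "A")]
        null = estimate_null(
            twin, tmap, universe, n_permutations=500, seed=6,
            combine_on="raw",
        )
        sw = twin[0].weight + twin[1].weight
        assert null.df_effective < sw

    def test_seeded_determinism(self):
        pathways, tmap, universe = self._disjoint_data(seed=7)
        a = estimate_null(pathways, tmap, universe,
                          n_permutations=200, seed=3)
        b = estimate_null(pathways, tmap, universe,
                          n_permutations=200, seed=3)
        assert a.scale == b.scale and a.df_effective == b.df_effective
        np.testing.assert_array_equal(a.perm_T, b.perm_T)

    def test_too_few_permutations_rejected(self):
        pathways, tmap, universe = self._disjoint_data(seed=8)
        with pytest.raises(ValidationError):
            estimate_null(pathways, tmap, universe, n_permutations=50)


class TestMonotonicity:
    def test_swapping_in_pathway_target_never_raises_p(self):
        # hold |T| fixed: replace a non-pathway target with a pathway gene
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(200)]
        pw_genes = frozenset(genes[:40])
        for _ in range(20):
            others = frozenset(
                genes[i] for i in rng.choice(200, size=80, replace=False)
            )
            tmap = TargetMap(mode="VMT", targets={
                "m": others, "bg": frozenset(genes)})
            universe = build_universe(tmap)
            pw = pathway("P1", pw_genes)
            base = fisher_one_tailed(
                build_contingency("m", pw, tmap, universe)
            )
            out_gene = next(iter(others - pw_genes), None)
            in_gene = next(iter(pw_genes - others), None)
            if out_gene is None or in_gene is None:
                continue
            swapped = (others - {out_gene}) | {in_gene}
            tmap2 = TargetMap(mode="VMT", targets={
                "m": frozenset(swapped), "bg": frozenset(genes)})
            after = fisher_one_tailed(
                build_contingency("m", pw, tmap2, universe)
            )
            assert after <= base + 1e-15


class TestAnalysisOrchestration:
    def test_empty_target_mirnas_skipped_not_scored(self, small_scenario):
        ds = simulate(small_scenario)
        targets = dict(ds.vmt.targets)
        targets["mir-empty"] = frozenset()
        tmap = TargetMap(mode="VMT", targets=targets)
        res = enrichment_analysis(
            ds.pathways, tmap, n_permutations=100, seed=0
        )
        assert res.skipped_mirnas == ["mir-empty"]
        assert all(s.mirna != "mir-empty" for s in res.scores)

    def test_scores_ranked_and_pairs_complete(self, small_scenario):
        ds = simulate(small_scenario)
        res = enrichment_analysis(
            ds.pathways, ds.vmt, n_permutations=100, seed=0
        )
        assert len(res.pairs) == len(res.scores) * len(res.pathway_ids)
        assert [s.rank for s in res.scores] == list(
            range(1, len(res.scores) + 1)
        )
        for s in res.scores:
            assert 0 < s.p_combined <= 1
            assert s.neg_log_p == pytest.approx(-math.log10(s.p_combined))
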