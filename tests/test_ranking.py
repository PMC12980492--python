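"""Candidate filters, cosine ranking, aggregation arithmetic, MCES, bootstrap."""

import itertools

import numpy as np
import pytest

from specview.chemio import parse_molecule
from specview.ranking import (
    CandidateSet,
    McesSizeError,
    RankingResult,
    aggregate_average_rank,
    aggregate_reciprocal_rank,
    bootstrap_ci,
    build_candidates,
    cosine,
    heavy_atom_graph,
    mces_at_1,
    mces_distance,
    rank_after_aggregation,
    rank_at_k,
    rank_candidates,
    split_ranking_view,
)
from specview.synthetic import SubformulaProfileEmbedder, consensus_advantage_fixture


def mces_oracle(a, b):
    """Exhaustive injective-node-mapping search for the MCES distance."""
    ga, gb = heavy_atom_graph(a), heavy_atom_graph(b)
    if ga.number_of_nodes() > gb.number_of_nodes():
        ga, gb = gb, ga
    best = 0
    nodes_a = list(ga.nodes)
    for perm in itertools.permutations(gb.nodes, len(nodes_a)):
        phi = dict(zip(nodes_a, perm))
        count = 0
        for u, v in ga.edges:
            pu, pv = phi[u], phi[v]
            if (
                gb.has_edge(pu, pv)
                and ga.nodes[u]["symbol"] == gb.nodes[pu]["symbol"]
                and ga.nodes[v]["symbol"] == gb.nodes[pv]["symbol"]
                and ga.edges[u, v]["order"] == gb.edges[pu, pv]["order"]
            ):
                count += 1
        best = max(best, count)
    return ga.number_of_edges() + gb.number_of_edges() - 2 * best


class TestBuildCandidates:
    def _pool(self):
        return [
            parse_molecule(s, f"p{i}")
            for i, s in enumerate(["CCO", "COC", "CCCO", "CC(C)O", "c1ccccc1"])
        ]

    def test_mass_window_arithmetic(self):
        target = parse_molecule("CCO", "ethanol")  # 46.0419 Da
        pool = self._pool()
        cs = build_candidates(target, pool, mode="by_mass")
        smiles = {m.smiles for m in cs.candidates}
        assert target.smiles in smiles
        # dimethyl ether: same formula, identical mass -> 0 ppm, included
        assert parse_molecule("COC", "x").smiles in smiles
        # propanol is ~350000 ppm away -> excluded
        assert parse_molecule("CCCO", "x").smiles not in smiles
        for m in cs.candidates:  # recompute the 10 ppm check independently
            ppm = abs(m.monoisotopic_mass - target.monoisotopic_mass) / target.monoisotopic_mass * 1e6
            assert ppm <= 10.0

    def test_formula_mode_isomers_only(self):
        target = parse_molecule("CCCO", "propanol")
        cs = build_candidates(target, self._pool(), mode="by_formula")
        formulas = {m.formula.format() for m in cs.candidates}
        assert formulas == {"C3H8O"}
        # pool's propanol copy dedupes against the target by canonical SMILES
        assert len(cs.candidates) == 2  # target + isopropanol

    def test_empty_pool_target_only(self):
        target = parse_molecule("CCO", "ethanol")
        cs = build_candidates(target, [], mode="by_mass")
        assert [m.smiles for m in cs.candidates] == [target.smiles]

    def test_trim_keeps_target_and_nearest(self):
        target = parse_molecule("CCO", "ethanol")
        pool = [parse_molecule("COC", f"d{i}") for i in range(5)]
        cs = build_candidates(target, pool, mode="by_mass", max_n=2)
        assert len(cs.candidates) == 2
        assert cs.candidates[0].smiles == target.smiles


class TestRankCandidates:
    def test_matches_sort_by_cosine_oracle(self):
        fix = consensus_advantage_fixture()
        emb = SubformulaProfileEmbedder()
        res = rank_candidates(fix.consensus, fix.candidates, "mol-cs", emb)
        z = emb.embed_spectrum(fix.consensus, "cs")
        oracle_scores = [
            cosine(z, emb.embed_molecule(m, "mol")) for m in fix.candidates.candidates
        ]
        expected = [
            fix.candidates.candidates[i].smiles
            for i in np.argsort(-np.array(oracle_scores), kind="stable")
        ]
        assert [m.smiles for m, _ in res.ordered] == expected
        assert all(a >= b for (_, a), (_, b) in zip(res.ordered, res.ordered[1:]))

    def test_single_candidate_rank_one(self):
        fix = consensus_advantage_fixture()
        solo = CandidateSet("q", [fix.target], "by_mass", target_id="butanol")
        res = rank_candidates(fix.consensus, solo, "mol-cs", SubformulaProfileEmbedder())
        assert res.rank_of_target == 1

    def test_duplicate_of_target_forces_tie_pessimism(self):
        fix = consensus_advantage_fixture()
        twin = parse_molecule("CCCCO", "twin")
        cands = CandidateSet("q", [fix.target, twin], "by_mass", target_id="butanol")
        res = rank_candidates(fix.consensus, cands, "mol-cs", SubformulaProfileEmbedder())
        assert res.rank_of_target == 2  # tied scores -> worst rank in group

    def test_unknown_view_rejected(self):
        with pytest.raises(ValueError, match="unknown ranking view"):
            split_ranking_view("graph-spec")


class TestRankAtK:
    def test_counting(self):
        results = [RankingResult(f"q{i}", [], r) for i, r in enumerate([1, 7, 21, 2])]
        assert rank_at_k(results, 5) == 50.0
        assert rank_at_k(results, 1) == 25.0
        assert rank_at_k(results, 20) == 75.0

    def test_k_beyond_all_ranks_is_total_recall(self):
        results = [RankingResult(f"q{i}", [], r) for i, r in enumerate([3, 9, 2])]
        assert rank_at_k(results, 100) == 100.0

    def test_monotone_in_k(self):
        rng = np.random.default_rng(0)
        results = [
            RankingResult(f"q{i}", [], int(r))
            for i, r in enumerate(rng.integers(1, 30, size=50))
        ]
        values = [rank_at_k(results, k) for k in (1, 5, 20)]
        assert values[0] <= values[1] <= values[2]

    def test_unranked_counts_as_failure(self):
        results = [RankingResult("a", [], 1), RankingResult("b", [], None)]
        assert rank_at_k(results, 1) == 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_at_k([], 1)


class TestAggregation:
    def test_average_rank_arithmetic(self):
        mat = np.array([[2, 4, 6], [1, 1, 9], [3, 2, 1]])
        order, scores = aggregate_average_rank(mat)
        assert scores.tolist() == [4.0, pytest.approx(11 / 3), 2.0]
        assert order.tolist() == [2, 1, 0]

    def test_reciprocal_rank_arithmetic(self):
        mat = np.array([[1, 3, 2]])
        _, scores = aggregate_reciprocal_rank(mat)
        assert scores[0] == pytest.approx(1 + 1 / 3 + 1 / 2)
        assert scores[0] == pytest.approx(1.83333, abs=1e-5)

    def test_single_hit_beats_uniform_second(self):
        # candidate A ranked (1, 10): score 1.1; candidate B ranked (2, 2): 1.0
        mat = np.array([[1, 10], [2, 2]])
        order, scores = aggregate_reciprocal_rank(mat)
        assert scores.tolist() == [1.1, 1.0]
        assert order.tolist() == [0, 1]

    def test_single_spectrum_degenerates_to_its_order(self):
        mat = np.array([[3], [1], [2]])
        order_avg, _ = aggregate_average_rank(mat)
        order_rec, _ = aggregate_reciprocal_rank(mat)
        assert order_avg.tolist() == order_rec.tolist() == [1, 2, 0]

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(1)
        mat = rng.integers(1, 10, size=(5, 4))
        perm = mat[:, rng.permutation(4)]
        for agg in (aggregate_average_rank, aggregate_reciprocal_rank):
            o1, s1 = agg(mat)
            o2, s2 = agg(perm)
            np.testing.assert_allclose(s1, s2)
            assert o1.tolist() == o2.tolist()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="aggregation"):
            rank_after_aggregation(np.array([[1], [2]]), 0, "median")


class TestMces:
    PAIRS = [
        ("CC", "C"),          # ethane vs methane: forced distance 1
        ("CCO", "COC"),       # ethanol vs dimethyl ether
        ("CCO", "CCO"),       # identical
        ("CCCC", "CC(C)C"),   # butane vs isobutane
        ("C1CC1", "CCC"),     # cyclopropane vs propane
        ("CC=O", "CCO"),      # bond-order mismatch
        ("c1ccccc1", "C1CCCCC1"),  # aromatic vs saturated ring
        ("NCC(=O)O", "CCC(=O)O"),  # glycine vs propionic acid
    ]

    @pytest.mark.parametrize("sa,sb", PAIRS)
    def test_matches_enumeration_oracle(self, sa, sb):
        a, b = parse_molecule(sa, "a"), parse_molecule(sb, "b")
        assert mces_distance(a, b) == mces_oracle(a, b)

    @pytest.mark.parametrize("sa,sb", PAIRS[:4])
    def test_symmetric(self, sa, sb):
        a, b = parse_molecule(sa, "a"), parse_molecule(sb, "b")
        assert mces_distance(a, b) == mces_distance(b, a)

    def test_identity_zero(self):
        m = parse_molecule("OC(=O)CCC(=O)O", "succinate")
        assert mces_distance(m, m) == 0

    def test_size_cap_raises(self):
        big = parse_molecule("CCCCCCCCCCCCCC", "c14")
        small = parse_molecule("CC", "ethane")
        with pytest.raises(McesSizeError, match="cap"):
            mces_distance(big, small)

    def test_mces_at_1_is_mean(self):
        a = parse_molecule("CCO", "a")
        b = parse_molecule("COC", "b")
        results = [
            RankingResult("q1", [(a, 1.0)], 1, target=a),  # top1 == target: 0
            RankingResult("q2", [(b, 1.0)], 2, target=a),  # distance 2
        ]
        assert mces_at_1(results) == pytest.approx(
            (0 + mces_distance(a, b)) / 2
        )


class TestBootstrap:
    def test_zero_variance_degenerate_interval(self):
        ranks = np.ones(20)
        lo, hi = bootstrap_ci(ranks, lambda v: 100.0 * np.mean(v <= 1), seed=0)
        assert (lo, hi) == (100.0, 100.0)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(2)
        ranks = rng.integers(1, 10, size=30)
        a = bootstrap_ci(ranks, np.mean, n_resamples=500, seed=7)
        b = bootstrap_ci(ranks, np.mean, n_resamples=500, seed=7)
        assert a == b

    def test_interval_contains_point_estimate_for_mean_metrics(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            ranks = rng.integers(1, 20, size=40)
            metric = lambda v: 100.0 * np.mean(v <= 5)
            lo, hi = bootstrap_ci(ranks, metric, n_resamples=1000, seed=trial)
            assert lo <= metric(ranks) <= hi
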