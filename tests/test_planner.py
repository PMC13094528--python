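"""Pareto front algebra and MCTS pathway search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from enzedit.chemgraph import parse_molecule
from enzedit.enzyme_eval import ECNumber
from enzedit.fixtures import SyntheticUniverse, make_putrescine_dag, oracle_predictor
from enzedit.planner import (
    AndOrTree,
    ParetoFront,
    PathwayCandidate,
    PathwayStep,
    PlannerConfig,
    aggregate_objectives,
    dominates,
    mcts_search,
    pareto_insert,
    ra_score,
    substrate_similarity,
)

GROUND_TRUTH_EC_ROUTES = sorted(
    [
        ("3.5.3.11", "4.1.1.19"),
        ("3.5.1.53", "3.5.3.12", "4.1.1.19"),
        ("4.1.1.17", "3.5.3.1"),
    ]
)


def _step(conf=0.8, sim=0.5, product="CCO", ec="1.1.1.1"):
    return PathwayStep(
        product=product,
        precursors=("CC=O",),
        ec=ECNumber.parse(ec),
        confidence=conf,
        substrate_sim=sim,
    )


def _cand(length, ra, sim):
    steps = tuple(_step(conf=ra, sim=sim, product=f"m{i}") for i in range(length))
    return PathwayCandidate(steps=steps, complete=True)


class TestObjectives:
    def test_single_step_vector(self):
        assert aggregate_objectives([_step(0.8, 0.5)]) == (1, 0.8, 0.5)

    def test_empty_pathway_convention(self):
        assert aggregate_objectives([]) == (0, 1.0, 1.0)

    def test_three_steps_are_arithmetic_means(self):
        steps = [_step(0.9, 0.2), _step(0.6, 0.8), _step(0.3, 0.5)]
        l, ra, sim = aggregate_objectives(steps)
        assert l == 3
        assert ra == pytest.approx((0.9 + 0.6 + 0.3) / 3)
        assert sim == pytest.approx((0.2 + 0.8 + 0.5) / 3)

    def test_ra_score_geometric_mean(self):
        assert ra_score([1.0, 1.0]) == pytest.approx(1.0)
        assert ra_score([0.25, 1.0]) == pytest.approx(0.5)
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.uniform(0.01, 1.0, size=int(rng.integers(1, 9)))
            assert ra_score(v) == pytest.approx(np.exp(np.mean(np.log(v))))

    def test_substrate_similarity_is_best_match(self):
        blocks = [parse_molecule(s) for s in ("CCO", "CCN", "CCCC", "c1ccccc1")]
        m = parse_molecule("CCO")
        assert substrate_similarity(m, blocks) == 1.0
        probe = parse_molecule("CCOC")
        from enzedit.chemgraph import tanimoto_similarity

        brute = max(tanimoto_similarity(probe, b) for b in blocks)
        assert substrate_similarity(probe, blocks) == pytest.approx(brute)
        assert substrate_similarity(probe, blocks[:1]) == pytest.approx(
            tanimoto_similarity(probe, blocks[0])
        )


class TestDominance:
    def test_strictly_better_everywhere(self):
        assert dominates((2, 0.9, 0.8), (3, 0.8, 0.7))

    def test_equal_vectors_do_not_dominate(self):
        assert not dominates((2, 0.9, 0.8), (2, 0.9, 0.8))

    def test_trade_off_is_incomparable(self):
        assert not dominates((2, 0.9, 0.6), (3, 0.8, 0.7))
        assert not dominates((3, 0.8, 0.7), (2, 0.9, 0.6))

    @given(
        st.tuples(st.integers(0, 6), st.floats(0, 1), st.floats(0, 1)),
        st.tuples(st.integers(0, 6), st.floats(0, 1), st.floats(0, 1)),
    )
    def test_antisymmetric(self, a, b):
        assert not (dominates(a, b) and dominates(b, a))


class TestParetoInsert:
    def test_dominated_candidate_rejected(self):
        front = ParetoFront()
        front.insert(_cand(2, 0.9, 0.8))
        pareto_insert(front, _cand(3, 0.8, 0.7))
        assert len(front) == 1

    def test_dominating_candidate_evicts(self):
        front = ParetoFront()
        front.insert(_cand(3, 0.8, 0.7))
        pareto_insert(front, _cand(2, 0.9, 0.8))
        assert [c.objectives for c in front] == [(2, 0.9, 0.8)]

    def test_equals_brute_force_under_any_insertion_order(self):
        rng = np.random.default_rng(5)
        cands = [
            _cand(int(rng.integers(1, 6)), round(float(rng.random()), 3),
                  round(float(rng.random()), 3))
            for _ in range(100)
        ]
        objs = [c.objectives for c in cands]
        brute = {
            o
            for o in objs
            if not any(dominates(p, o) for p in objs)
        }
        for perm_seed in range(5):
            order = np.random.default_rng(perm_seed).permutation(len(cands))
            front = ParetoFront()
            for i in order:
                front.insert(cands[i])
            assert {c.objectives for c in front} == brute
            assert front.check_valid()


class TestExpand:
    def test_and_children_match_universe_edges(self, putrescine):
        target = parse_molecule("NCCCCN")
        tree = AndOrTree(target, putrescine.building_blocks)
        blocks = [putrescine.molecules[b] for b in putrescine.building_blocks]
        kids = tree.expand(tree.root, oracle_predictor(putrescine), 10, set(), blocks)
        got = sorted((k.precursors[0].smiles, str(k.ec)) for k in kids)
        want = sorted(
            (pre[0], str(ec)) for pre, ec, _ in putrescine.reactions["NCCCCN"]
        )
        assert got == want

    def test_empty_prediction_marks_node_dead(self, putrescine):
        stranger = parse_molecule("c1ccccc1")
        tree = AndOrTree(stranger, putrescine.building_blocks)
        kids = tree.expand(
            tree.root, oracle_predictor(putrescine), 10, set(), []
        )
        assert kids == [] and tree.root.dead


class TestMctsSearch:
    def test_target_in_building_blocks_terminates_immediately(self, putrescine):
        blocks = [putrescine.molecules[b] for b in putrescine.building_blocks]
        front = mcts_search(blocks[0], oracle_predictor(putrescine), blocks)
        assert len(front) == 1
        (only,) = front
        assert only.complete and only.objectives == (0, 1.0, 1.0)

    def test_recovers_all_three_putrescine_routes(self, putrescine):
        blocks = [putrescine.molecules[b] for b in putrescine.building_blocks]
        target = parse_molecule("NCCCCN")
        for seed in range(5):
            front = mcts_search(
                target, oracle_predictor(putrescine), blocks, PlannerConfig(seed=seed)
            )
            assert sorted(c.ec_sequence for c in front) == GROUND_TRUTH_EC_ROUTES
            lengths = sorted(c.objectives[0] for c in front)
            assert lengths == [2, 2, 3]

    def test_front_matches_exhaustive_enumeration(self, putrescine):
        """On a universe small enough to enumerate, MCTS must return the
        true Pareto front of all complete pathways."""
        blocks = [putrescine.molecules[b] for b in putrescine.building_blocks]
        target = parse_molecule("NCCCCN")
        front = mcts_search(target, oracle_predictor(putrescine), blocks,
                            PlannerConfig(seed=1))
        # brute force: enumerate all pathways of the DAG
        def enumerate_routes(smi):
            if smi in putrescine.building_blocks:
                yield ()
                return
            for pre, ec, conf in putrescine.reactions[smi]:
                from enzedit.chemgraph import tanimoto_similarity

                sim = np.mean(
                    [
                        max(
                            tanimoto_similarity(putrescine.molecules[p], b)
                            for b in blocks
                        )
                        for p in pre
                    ]
                )
                head = (smi, pre, str(ec), conf, float(sim))
                for tails in itertools.product(*(enumerate_routes(p) for p in pre)):
                    yield (head,) + tuple(t for tail in tails for t in tail)

        all_objs = []
        for route in enumerate_routes("NCCCCN"):
            n = len(route)
            all_objs.append(
                (
                    n,
                    sum(s[3] for s in route) / n,
                    sum(s[4] for s in route) / n,
                )
            )
        true_front = {
            o for o in all_objs if not any(dominates(p, o) for p in all_objs)
        }
        assert len(front) == len(true_front)
        for o in true_front:
            assert any(
                c.objectives[0] == o[0]
                and c.objectives[1] == pytest.approx(o[1])
                and c.objectives[2] == pytest.approx(o[2])
                for c in front
            )

    def test_noisy_predictor_front_contains_only_complete_pathways(self, putrescine):
        blocks = [putrescine.molecules[b] for b in putrescine.building_blocks]
        target = parse_molecule("NCCCCN")
        for seed in range(5):
            front = mcts_search(
                target,
                oracle_predictor(putrescine, noise=0.5, seed=seed),
                blocks,
                PlannerConfig(seed=seed),
            )
            assert front.check_valid()
            for c in front:
                assert c.complete
                assert c.objectives == aggregate_objectives(c.steps)
                assert c.objectives[0] <= 10

    def test_low_confidence_complete_route_still_returned(self):
        """Completeness beats step confidence: a complete route with low
        confidence must win over a dead-end branch with high confidence."""
        ec = ECNumber.parse("1.1.1.1")
        uni = SyntheticUniverse(
            molecules={s: parse_molecule(s) for s in ("CCCO", "CCC=O", "CCO", "OCC(O)CO")},
            reactions={
                "CCCO": [
                    (("OCC(O)CO",), ec, 0.99),  # dead end, not a block
                    (("CCC=O",), ec, 0.10),
                ],
                "CCC=O": [(("CCO",), ec, 0.10)],
                "OCC(O)CO": [(("CCC=O",), ec, 0.01)],
            },
            building_blocks={"CCO"},
        )
        blocks = [uni.molecules["CCO"]]
        front = mcts_search(
            parse_molecule("CCCO"), oracle_predictor(uni), blocks, PlannerConfig(seed=0)
        )
        assert any(
            c.complete and c.ec_sequence and c.objectives[0] == 2 for c in front
        )

    def test_deterministic_per_seed(self, putrescine):
        blocks = [putrescine.molecules[b] for b in putrescine.building_blocks]
        target = parse_molecule("NCCCCN")
        a = mcts_search(target, oracle_predictor(putrescine), blocks, PlannerConfig(seed=9))
        b = mcts_search(target, oracle_predictor(putrescine), blocks, PlannerConfig(seed=9))
        assert [c.steps for c in a] == [c.steps for c in b]

    def test_empty_building_blocks_rejected(self, putrescine):
        with pytest.raises(ValueError):
            mcts_search(parse_molecule("NCCCCN"), oracle_predictor(putrescine), [])
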