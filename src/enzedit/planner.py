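"""Multi-step enzymatic retrosynthesis planning.

The search space is an AND-OR tree: OR-nodes are molecules (alternative
disconnections), AND-nodes are single retro steps — a precursor set plus
the EC number of the catalyzing enzyme.  Monte Carlo tree search expands
the tree under a budget while a Pareto front collects complete pathways
under three objectives:

* pathway length (minimize),
* retrosynthetic accessibility (RAscore — the generator's per-step
  confidence, averaged over steps; maximize),
* substrate similarity (best Tanimoto match of each precursor against
  the building-block set, averaged; maximize).

Selection scalarizes the three objectives with fresh random weights each
iteration (UCT on the scalarized value), which keeps exploration spread
across the front instead of collapsing onto one trade-off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

from .chemgraph import IndexedMolecule, canonical_smiles, tanimoto_similarity
from .enzyme_eval import ECNumber

__all__ = [
    "SingleStepPredictor",
    "PlannerConfig",
    "PathwayStep",
    "PathwayCandidate",
    "ParetoFront",
    "AndOrTree",
    "aggregate_objectives",
    "dominates",
    "pareto_insert",
    "ra_score",
    "substrate_similarity",
    "mcts_search",
    "pathway_json",
]


class SingleStepPredictor(Protocol):
    def predict(
        self, product: IndexedMolecule, beam_size: int = 10
    ) -> "list[tuple[list[IndexedMolecule], ECNumber, float]]": ...


@dataclass(frozen=True)
class PlannerConfig:
    beam_size: int = 10
    max_depth: int = 10
    iterations: int = 100
    pathway_top_k: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("beam_size", "max_depth", "iterations", "pathway_top_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def ra_score(token_confidences: Sequence[float]) -> float:
    """Geometric mean of per-token confidences — the per-step accessibility."""
    if len(token_confidences) == 0:
        raise ValueError("ra_score needs at least one confidence")
    logs = [math.log(c) for c in token_confidences]
    return math.exp(sum(logs) / len(logs))


def substrate_similarity(
    mol: IndexedMolecule, building_blocks: Sequence[IndexedMolecule]
) -> float:
    """Tanimoto similarity to the best-matching building-block entry."""
    if not building_blocks:
        raise ValueError("building block set is empty")
    return max(tanimoto_similarity(mol, b) for b in building_blocks)


@dataclass(frozen=True)
class PathwayStep:
    product: str  # canonical SMILES
    precursors: tuple[str, ...]
    ec: Optional[ECNumber]
    confidence: float
    substrate_sim: float


@dataclass(frozen=True)
class PathwayCandidate:
    steps: tuple[PathwayStep, ...]
    complete: bool

    @property
    def objectives(self) -> tuple[float, float, float]:
        return aggregate_objectives(self.steps)

    @property
    def ec_sequence(self) -> tuple[str, ...]:
        return tuple(str(s.ec) for s in self.steps)


def aggregate_objectives(steps: Sequence[PathwayStep]) -> tuple[float, float, float]:
    """(length, mean RAscore, mean substrate similarity); empty -> (0, 1, 1)."""
    if not steps:
        return (0, 1.0, 1.0)
    n = len(steps)
    return (
        n,
        sum(s.confidence for s in steps) / n,
        sum(s.substrate_sim for s in steps) / n,
    )


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Pareto dominance under (min length, max RAscore, max similarity)."""
    no_worse = a[0] <= b[0] and a[1] >= b[1] and a[2] >= b[2]
    better = a[0] < b[0] or a[1] > b[1] or a[2] > b[2]
    return no_worse and better


class ParetoFront:
    """Mutually non-dominated pathway candidates; order-independent."""

    def __init__(self):
        self._members: list[PathwayCandidate] = []
        self._keys: set = set()

    def __iter__(self):
        return iter(self._members)

    def __len__(self):
        return len(self._members)

    @property
    def members(self) -> list[PathwayCandidate]:
        return list(self._members)

    def insert(self, candidate: PathwayCandidate) -> bool:
        key = (candidate.steps, candidate.complete)
        if key in self._keys:
            return False
        obj = candidate.objectives
        for m in self._members:
            if dominates(m.objectives, obj):
                return False
        kept = [m for m in self._members if not dominates(obj, m.objectives)]
        removed = set(self._keys) - {(m.steps, m.complete) for m in kept}
        self._keys -= removed
        kept.append(candidate)
        self._members = kept
        self._keys.add(key)
        return True

    def check_valid(self) -> bool:
        for a in self._members:
            for b in self._members:
                if a is not b and dominates(a.objectives, b.objectives):
                    return False
        return True


def pareto_insert(front: ParetoFront, candidate: PathwayCandidate) -> ParetoFront:
    """Functional wrapper over :meth:`ParetoFront.insert`."""
    front.insert(candidate)
    return front


def _crowding_trim(members: list[PathwayCandidate], k: int) -> list[PathwayCandidate]:
    """NSGA-II-style crowding-distance truncation of a single front."""
    if len(members) <= k:
        return members
    objs = [m.objectives for m in members]
    n = len(members)
    dist = [0.0] * n
    for dim in range(3):
        order = sorted(range(n), key=lambda i: objs[i][dim])
        lo, hi = objs[order[0]][dim], objs[order[-1]][dim]
        span = hi - lo
        dist[order[0]] = dist[order[-1]] = float("inf")
        if span == 0:
            continue
        for r in range(1, n - 1):
            dist[order[r]] += (objs[order[r + 1]][dim] - objs[order[r - 1]][dim]) / span
    ranked = sorted(range(n), key=lambda i: (-dist[i], objs[i]))
    return [members[i] for i in sorted(ranked[:k])]


# ---------------------------------------------------------------------------
# AND-OR tree


@dataclass
class AndNode:
    parent: "OrNode"
    precursors: list["OrNode"]
    ec: Optional[ECNumber]
    confidence: float
    substrate_sim: float
    visits: int = 0
    value: float = 0.0


@dataclass
class OrNode:
    smiles: str
    molecule: IndexedMolecule
    is_block: bool
    children: list[AndNode] = field(default_factory=list)
    expanded: bool = False
    dead: bool = False
    visits: int = 0
    value: float = 0.0


class AndOrTree:
    """OR-nodes keyed by canonical SMILES (merged globally); the root is
    the target.  Acyclicity along any root-to-leaf path is enforced at
    expansion and during pathway harvesting."""

    def __init__(self, target: IndexedMolecule, building_blocks: set[str]):
        self.blocks = building_blocks
        self.nodes: dict[str, OrNode] = {}
        self.root = self._get_or_node(target)

    def _get_or_node(self, mol: IndexedMolecule) -> OrNode:
        smi = canonical_smiles(mol)
        if smi not in self.nodes:
            self.nodes[smi] = OrNode(smiles=smi, molecule=mol, is_block=smi in self.blocks)
        return self.nodes[smi]

    def expand(
        self,
        node: OrNode,
        predictor: SingleStepPredictor,
        beam_size: int,
        path: set[str],
        block_mols: list[IndexedMolecule],
    ) -> list[AndNode]:
        """One predictor call; AND-children deduplicated by canonical
        precursor set + EC, path-repeating candidates rejected."""
        if node.expanded:
            return node.children
        node.expanded = True
        try:
            candidates = predictor.predict(node.molecule, beam_size=beam_size)
        except Exception:
            node.dead = True
            return []
        seen: set = set()
        new: list[AndNode] = []
        for precursors, ec, conf in candidates[:beam_size]:
            try:
                smis = tuple(sorted(canonical_smiles(m) for m in precursors))
            except Exception:
                continue  # invalid candidate molecule — filtered
            key = (smis, str(ec))
            if key in seen or not smis:
                continue
            seen.add(key)
            if any(s in path for s in smis):
                continue  # would reintroduce a molecule already on the path
            kids = [self._get_or_node(m) for m in precursors]
            sim = sum(
                substrate_similarity(m, block_mols) for m in precursors
            ) / len(precursors)
            new.append(
                AndNode(
                    parent=node,
                    precursors=kids,
                    ec=ec,
                    confidence=float(conf),
                    substrate_sim=sim,
                )
            )
        node.children = new
        if not new:
            node.dead = True
        return new


# ---------------------------------------------------------------------------
# search


def _harvest(
    tree: AndOrTree, max_depth: int, limit: int = 5000
) -> list[PathwayCandidate]:
    """Enumerate complete pathways in the expanded tree (bounded)."""
    out: list[PathwayCandidate] = []

    def routes(node: OrNode, path: frozenset, depth: int):
        """Yield step-tuples that fully reduce `node` to building blocks."""
        if node.is_block:
            yield ()
            return
        if depth >= max_depth or not node.expanded or node.dead:
            return
        for child in node.children:
            if any(p.smiles in path for p in child.precursors):
                continue
            step = PathwayStep(
                product=node.smiles,
                precursors=tuple(sorted(p.smiles for p in child.precursors)),
                ec=child.ec,
                confidence=child.confidence,
                substrate_sim=child.substrate_sim,
            )
            sub: list[tuple[PathwayStep, ...]] = [()]
            feasible = True
            for p in child.precursors:
                branches = list(routes(p, path | {node.smiles}, depth + 1))
                if not branches:
                    feasible = False
                    break
                sub = [a + b for a in sub for b in branches][:limit]
            if feasible:
                for tail in sub:
                    yield (step,) + tail

    for steps in routes(tree.root, frozenset(), 0):
        out.append(PathwayCandidate(steps=steps, complete=True))
        if len(out) >= limit:
            break
    return out


def _scalarize(obj: tuple[float, float, float], w: np.ndarray, max_depth: int) -> float:
    length_term = 1.0 - obj[0] / (max_depth + 1)
    return float(w[0] * length_term + w[1] * obj[1] + w[2] * obj[2])


def mcts_search(
    target: IndexedMolecule,
    predictor: SingleStepPredictor,
    building_blocks: Sequence[IndexedMolecule],
    config: PlannerConfig = PlannerConfig(),
) -> ParetoFront:
    """MCTS over the AND-OR tree; returns the Pareto front of complete
    pathways, trimmed to ``pathway_top_k`` by crowding distance.

    Fully deterministic per (seed, config, predictor).  A target already
    in the building-block set yields the single empty pathway.
    """
    if not building_blocks:
        raise ValueError("building block set is empty")
    block_mols = list(building_blocks)
    blocks = {canonical_smiles(b) for b in block_mols}
    target_smi = canonical_smiles(target)

    front = ParetoFront()
    if target_smi in blocks:
        front.insert(PathwayCandidate(steps=(), complete=True))
        return front

    rng = np.random.default_rng(config.seed)
    tree = AndOrTree(target, blocks)
    c_uct = 1.4

    for _ in range(config.iterations):
        w = rng.dirichlet([1.0, 1.0, 1.0])
        # --- selection: walk OR->AND->OR by scalarized UCT
        node = tree.root
        path: set[str] = set()
        trail: list = [node]
        depth = 0
        while node.expanded and not node.dead and depth < config.max_depth:
            live = [
                a
                for a in node.children
                if not all(p.is_block or p.dead for p in a.precursors)
                or any(p.is_block for p in a.precursors)
            ]
            if not node.children:
                break
            pool = node.children
            tot = max(1, node.visits)

            def uct(a: AndNode) -> float:
                exploit = a.value / a.visits if a.visits else 0.0
                explore = c_uct * math.sqrt(math.log(tot + 1) / (a.visits + 1))
                return exploit + explore

            scores = [uct(a) for a in pool]
            best = max(range(len(pool)), key=lambda i: (scores[i], -i))
            chosen = pool[best]
            trail.append(chosen)
            path.add(node.smiles)
            frontier = [
                p for p in chosen.precursors if not p.is_block and not p.dead
            ]
            unexpanded = [p for p in frontier if not p.expanded]
            if unexpanded:
                node = unexpanded[0]
            elif frontier:
                node = frontier[int(rng.integers(0, len(frontier)))]
            else:
                node = chosen.precursors[0]
                break
            trail.append(node)
            depth += 1

        # --- expansion
        if not node.expanded and not node.is_block and depth < config.max_depth:
            tree.expand(node, predictor, config.beam_size, path, block_mols)

        # --- rollout: greedy rank-1 descent from the new node
        reward_steps: list[PathwayStep] = []
        roll = node
        roll_path = set(path) | {roll.smiles}
        for _ in range(config.max_depth - depth):
            if roll.is_block or roll.dead:
                break
            if not roll.expanded:
                tree.expand(roll, predictor, config.beam_size, roll_path, block_mols)
            if not roll.children:
                break
            a = max(roll.children, key=lambda x: x.confidence)
            reward_steps.append(
                PathwayStep(
                    product=roll.smiles,
                    precursors=tuple(sorted(p.smiles for p in a.precursors)),
                    ec=a.ec,
                    confidence=a.confidence,
                    substrate_sim=a.substrate_sim,
                )
            )
            nxt = [p for p in a.precursors if not p.is_block]
            if not nxt:
                break
            roll = nxt[0]
            if roll.smiles in roll_path:
                break
            roll_path.add(roll.smiles)

        reward = _scalarize(aggregate_objectives(reward_steps), w, config.max_depth)

        # --- backpropagation along the selection trail
        for item in trail:
            item.visits += 1
            item.value += reward

        # --- harvest complete pathways into the front
        for cand in _harvest(tree, config.max_depth):
            front.insert(cand)
        assert front.check_valid()

    members = _crowding_trim(front.members, config.pathway_top_k)
    trimmed = ParetoFront()
    for m in members:
        trimmed.insert(m)
    return trimmed


def pathway_json(front: ParetoFront) -> str:
    """Serialize a front as a typed OR/AND node-edge JSON graph."""
    pathways = []
    for cand in sorted(front, key=lambda c: (c.objectives[0], -c.objectives[1])):
        length, ra, sim = cand.objectives
        pathways.append(
            {
                "complete": cand.complete,
                "objectives": {"length": length, "ra_score": ra, "substrate_sim": sim},
                "steps": [
                    {
                        "type": "AND",
                        "product": s.product,
                        "precursors": list(s.precursors),
                        "ec": str(s.ec) if s.ec else None,
                        "confidence": s.confidence,
                        "substrate_sim": s.substrate_sim,
                    }
                    for s in cand.steps
                ],
            }
        )
    return json.dumps({"pathways": pathways}, sort_keys=True, indent=1)
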