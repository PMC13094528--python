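"""Seeded synthetic data: the offline test bed for every other module.

Three generators:

* :func:`make_reaction_fixtures` — atom-mapped toy reactions built
  *constructively*: a known random edit script is applied to a small
  molecule and the resulting components become the reactants, so the
  extraction target is unambiguous by construction and no external atom
  mapper is involved.
* :func:`make_putrescine_dag` — the putrescine biosynthesis network
  (three parallel routes from L-arginine, real metabolite structures,
  literature EC numbers) as a planner ground truth.
* :func:`oracle_predictor` — a single-step predictor that replays a
  synthetic reaction universe, optionally salted with ranked distractor
  candidates to stress beam filtering.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .chemgraph import IndexedMolecule, Reaction, canonical_smiles, parse_molecule
from .enzyme_eval import ECNumber
from .pretrain import SkipExample, _candidate_edits, _realize_leave
from .ssredits import (
    SSREdit,
    SSREditScript,
    ScriptError,
    apply_edits_tracked,
)

__all__ = [
    "ReactionFixtureSet",
    "SyntheticUniverse",
    "make_reaction_fixtures",
    "make_putrescine_dag",
    "oracle_predictor",
    "base_molecules",
]

STRUCTURAL_ACTIONS = (
    "DeleteBond",
    "ChangeBond",
    "AddBond",
    "AttachGroup",
    "LeaveGroup",
    "ChangeAtom",
)

# EC labels sampled onto fixture reactions (all appear in printed
# enzymatic-reaction literature; the assignment here is synthetic).
_FIXTURE_ECS = [
    "1.1.1.1",
    "1.1.1.103",
    "2.1.1.71",
    "2.6.1.1",
    "2.7.8.2",
    "3.1.1.1",
    "3.5.1.53",
    "3.8.1.5",
    "4.1.1.19",
    "4.1.1.24",
    "5.3.3.2",
    "6.3.2.49",
]


def base_molecules() -> list[str]:
    """Shipped pool of small, diverse, editable molecules."""
    text = resources.files("enzedit.data").joinpath("base_molecules.smi").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


@dataclass
class ReactionFixtureSet:
    """Atom-mapped reactions with known ground-truth scripts."""

    reactions: list[tuple[Reaction, SSREditScript]]
    coverage: dict[str, int] = field(default_factory=dict)

    def __len__(self):
        return len(self.reactions)


def _draw_of_type(
    mol: IndexedMolecule, action: str, rng: np.random.Generator
) -> Optional[SSREdit]:
    cands = _candidate_edits(mol, rng)[action]
    rng.shuffle(cands)
    for edit in cands:
        if action == "LeaveGroup":
            try:
                edit = _realize_leave(mol, edit)
            except ScriptError:
                continue
        try:
            apply_edits_tracked(mol, SSREditScript((edit, SSREdit("Terminate"))))
            return edit
        except ScriptError:
            continue
    return None


def make_reaction_fixtures(seed: int, n: int = 200) -> ReactionFixtureSet:
    """Build ``n`` (reaction, ground-truth script) pairs, cycling the six
    structural action types so each is represented at least ``n // 6``
    times (spec floor: 10 at n >= 60)."""
    if n < 60:
        raise ValueError("need n >= 60 for action-type coverage")
    rng = np.random.default_rng(seed)
    bases = base_molecules()
    reactions: list[tuple[Reaction, SSREditScript]] = []
    coverage = {a: 0 for a in STRUCTURAL_ACTIONS}
    k = 0
    attempts = 0
    while len(reactions) < n and attempts < 100 * n:
        attempts += 1
        action = STRUCTURAL_ACTIONS[k % len(STRUCTURAL_ACTIONS)]
        smi = bases[int(rng.integers(0, len(bases)))]
        mol = parse_molecule(smi)
        edit = _draw_of_type(mol, action, rng)
        if edit is None:
            continue
        edits = [edit]
        # optionally one extra random edit of any type for richer scripts
        if rng.random() < 0.3:
            other = STRUCTURAL_ACTIONS[int(rng.integers(0, len(STRUCTURAL_ACTIONS)))]
            extra = _draw_of_type(mol, other, rng)
            if extra is not None and extra != edit:
                trial = SSREditScript((edit, extra, SSREdit("Terminate")))
                try:
                    apply_edits_tracked(mol, trial)
                    edits.append(extra)
                except ScriptError:
                    pass
        ec = ECNumber.parse(_FIXTURE_ECS[int(rng.integers(0, len(_FIXTURE_ECS)))])
        script = SSREditScript(tuple(edits) + (SSREdit("Terminate"), SSREdit("EC", ec=ec)))
        try:
            components, id_map = apply_edits_tracked(mol, script)
        except ScriptError:
            continue
        reaction = Reaction(reactants=components, product=mol, atom_map=id_map, ec=ec)
        reactions.append((reaction, script))
        for e in edits:
            coverage[e.action] += 1
        k += 1
    if len(reactions) < n:
        raise RuntimeError(f"could only build {len(reactions)}/{n} fixture reactions")
    return ReactionFixtureSet(reactions=reactions, coverage=coverage)


# ---------------------------------------------------------------------------
# synthetic reaction universes


@dataclass
class SyntheticUniverse:
    """A directed retro-reaction network over canonical SMILES.

    ``reactions`` maps a product to candidate steps, each a tuple
    ``(precursor smiles tuple, ECNumber, confidence)``.  The network is a
    DAG in the retro direction and every non-building-block molecule has
    at least one outgoing reaction.
    """

    molecules: dict[str, IndexedMolecule]
    reactions: dict[str, list[tuple[tuple[str, ...], ECNumber, float]]]
    building_blocks: set[str]

    def __post_init__(self):
        for smi in self.molecules:
            if smi not in self.building_blocks and smi not in self.reactions:
                raise ValueError(f"non-building-block {smi} has no outgoing reaction")
        self._check_acyclic()

    def _check_acyclic(self):
        state: dict[str, int] = {}

        def visit(u: str):
            state[u] = 1
            for precursors, _, _ in self.reactions.get(u, []):
                for v in precursors:
                    if state.get(v) == 1:
                        raise ValueError(f"cyclic retro route through {v}")
                    if state.get(v) != 2:
                        visit(v)
            state[u] = 2

        for u in list(self.reactions):
            if state.get(u) != 2:
                visit(u)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticUniverse":
        d = json.loads(text)
        return cls(
            molecules={s: parse_molecule(s) for s in d["molecules"]},
            reactions={
                p: [
                    (tuple(pre), ECNumber.parse(ec), float(conf))
                    for pre, ec, conf in steps
                ]
                for p, steps in d["reactions"].items()
            },
            building_blocks=set(d["building_blocks"]),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "molecules": sorted(self.molecules),
                "building_blocks": sorted(self.building_blocks),
                "reactions": {
                    p: [[list(pre), str(ec), conf] for pre, ec, conf in steps]
                    for p, steps in sorted(self.reactions.items())
                },
            },
            sort_keys=True,
            indent=1,
        )


PUTRESCINE = "NCCCCN"
AGMATINE = "N=C(N)NCCCCN"
N_CARBAMOYLPUTRESCINE = "NCCCCNC(N)=O"
L_ORNITHINE = "NCCC[C@@H](N)C(=O)O"
L_ARGININE = "N=C(N)NCCC[C@@H](N)C(=O)O"


def make_putrescine_dag() -> SyntheticUniverse:
    """The putrescine biosynthesis network as a retro DAG.

    Three routes from L-arginine to putrescine:

    * I  (2 steps): arginine -(4.1.1.19)-> agmatine -(3.5.3.11)-> putrescine
    * II (3 steps): arginine -(4.1.1.19)-> agmatine -(3.5.3.12)->
      N-carbamoylputrescine -(3.5.1.53)-> putrescine
    * III (2 steps): arginine -(3.5.3.1)-> ornithine -(4.1.1.17)-> putrescine

    Structures are the real metabolites; step confidences are synthetic.
    """
    mols = {
        canonical_smiles(s): parse_molecule(s)
        for s in (PUTRESCINE, AGMATINE, N_CARBAMOYLPUTRESCINE, L_ORNITHINE, L_ARGININE)
    }
    c = canonical_smiles
    reactions = {
        c(PUTRESCINE): [
            ((c(AGMATINE),), ECNumber.parse("3.5.3.11"), 0.90),
            ((c(N_CARBAMOYLPUTRESCINE),), ECNumber.parse("3.5.1.53"), 0.98),
            ((c(L_ORNITHINE),), ECNumber.parse("4.1.1.17"), 0.80),
        ],
        c(AGMATINE): [
            ((c(L_ARGININE),), ECNumber.parse("4.1.1.19"), 0.95),
        ],
        c(N_CARBAMOYLPUTRESCINE): [
            ((c(AGMATINE),), ECNumber.parse("3.5.3.12"), 0.98),
        ],
        c(L_ORNITHINE): [
            ((c(L_ARGININE),), ECNumber.parse("3.5.3.1"), 0.92),
        ],
    }
    return SyntheticUniverse(
        molecules=mols,
        reactions=reactions,
        building_blocks={c(L_ARGININE)},
    )


class _UniversePredictor:
    """Replays a universe's true retro steps; optional ranked distractors."""

    def __init__(self, universe: SyntheticUniverse, noise: float, seed: int):
        if not 0 <= noise < 1:
            raise ValueError("noise must be in [0, 1)")
        self.universe = universe
        self.noise = noise
        self.seed = int(seed)

    def predict(self, product: IndexedMolecule, beam_size: int = 10):
        smi = canonical_smiles(product)
        steps = self.universe.reactions.get(smi)
        if steps is None:
            return []
        out = [
            ([parse_molecule(p) for p in precursors], ec, conf)
            for precursors, ec, conf in sorted(steps, key=lambda t: -t[2])
        ]
        if self.noise > 0:
            rng = np.random.default_rng(
                (self.seed * 2654435761 + zlib.crc32(smi.encode())) % (2**31)
            )
            if rng.random() < self.noise:
                # off-route distractor: a universe molecule that is not a
                # true precursor of this product, at a random rank
                true = {p for pre, _, _ in steps for p in pre}
                candidates = sorted(set(self.universe.molecules) - true - {smi})
                if candidates:
                    pick = candidates[int(rng.integers(0, len(candidates)))]
                    distract = (
                        [parse_molecule(pick)],
                        ECNumber.parse("1.1.1.1"),
                        float(rng.uniform(0.05, 0.3)),
                    )
                    pos = int(rng.integers(0, len(out) + 1))
                    out.insert(pos, distract)
        return out[:beam_size]


def oracle_predictor(universe: SyntheticUniverse, noise: float = 0.0, seed: int = 0):
    """A deterministic :class:`~enzedit.planner.SingleStepPredictor` over a
    synthetic universe."""
    return _UniversePredictor(universe, noise, seed)
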