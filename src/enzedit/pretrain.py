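"""Self-supervised pretraining corpus construction.

Three example builders over unlabeled SMILES:

* **FillMASK** — iteratively replace spans of 1-4 tokens with ``[MASK]``,
  left to right (tokens before a placed mask are frozen), up to five
  spans; the target lists each masked span behind its sentinel.
* **MakeSSREdits** — apply a random site-specific edit to a molecule and
  ask for the edit script given ``original>>edited``.
* **MakeSMILES** — the complementary direction: given the original SMILES
  and the edit script (joined by ``[SEP]``), produce the edited SMILES.

Under the same seed the latter two draw the same (molecule, edit) pair,
so one task's target provably transforms the shared input into the
other's — the property tests lean on this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from rdkit import Chem

from .chemgraph import (
    IndexedMolecule,
    TokenSequence,
    canonical_smiles,
    parse_molecule,
    tokenize_smiles,
)
from .ssredits import (
    ApplicationError,
    SSREdit,
    SSREditScript,
    ScriptError,
    apply_edits,
    serialize_script,
)

__all__ = [
    "TrainingExample",
    "SkipExample",
    "fillmask_example",
    "random_edit",
    "make_ssredits_example",
    "make_smiles_example",
    "build_corpus",
    "fragment_pool",
    "CONTEXT_LIMIT",
]

CONTEXT_LIMIT = 256
TASKS = (
    "FillMASK",
    "MakeSSREdits",
    "MakeSMILES",
    "RetroEdits",
    "ForwardSynthesis",
    "ECGeneration",
    "EnzymaticEdits",
)

MASK = "[MASK]"
SEP = "[SEP]"


class SkipExample(Exception):
    """Input unusable for the requested task; the caller draws another."""


@dataclass(frozen=True)
class TrainingExample:
    task: str
    input: TokenSequence
    target: TokenSequence
    seed: int

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if len(self.input) > CONTEXT_LIMIT or len(self.target) > CONTEXT_LIMIT:
            raise ValueError(f"example exceeds the {CONTEXT_LIMIT}-token context")

    def to_json(self) -> str:
        return json.dumps(
            {
                "task": self.task,
                "input": list(self.input),
                "target": list(self.target),
                "seed": self.seed,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "TrainingExample":
        d = json.loads(line)
        return cls(
            task=d["task"],
            input=TokenSequence(tuple(d["input"])),
            target=TokenSequence(tuple(d["target"])),
            seed=d["seed"],
        )


def _as_rng(rng) -> tuple[np.random.Generator, int]:
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng)), int(rng)
    return rng, -1


def fillmask_example(smiles: str, rng) -> TrainingExample:
    """Span-mask a tokenized SMILES; spans of 1-4 tokens, at most five."""
    rng, seed = _as_rng(rng)
    tokens = list(tokenize_smiles(smiles))
    if len(tokens) < 2:
        raise SkipExample("too short to mask")
    masked: list[str] = []
    spans: list[list[str]] = []
    cursor = 0
    for _ in range(5):
        if cursor >= len(tokens):
            break
        start = int(rng.integers(cursor, len(tokens)))
        length = int(rng.integers(1, min(4, len(tokens) - start) + 1))
        masked.extend(tokens[cursor:start])
        masked.append(MASK)
        spans.append(tokens[start : start + length])
        cursor = start + length
    masked.extend(tokens[cursor:])
    target: list[str] = []
    for span in spans:
        target.append(MASK)
        target.extend(span)
    return TrainingExample(
        "FillMASK", TokenSequence(tuple(masked)), TokenSequence(tuple(target)), seed
    )


def fragment_pool() -> list[str]:
    """The shipped pool of wildcard-anchored groups for random edits."""
    text = resources.files("enzedit.data").joinpath("fragments.smi").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


_CHARGE_TOGGLE = {("N", 0): "N+", ("N", 1): "N", ("O", 0): "O-", ("O", -1): "O", ("S", 0): "S+", ("S", 1): "S"}

_ORDER_TOKENS = {1.0: "-", 2.0: "=", 3.0: "#"}


def _candidate_edits(mol: IndexedMolecule, rng: np.random.Generator) -> dict[str, list[SSREdit]]:
    rd = mol.rdmol
    pool = fragment_pool()
    out: dict[str, list[SSREdit]] = {k: [] for k in
        ("DeleteBond", "ChangeBond", "AddBond", "AttachGroup", "LeaveGroup", "ChangeAtom")}

    def hs(idx: int) -> int:
        return rd.GetAtomWithIdx(idx).GetTotalNumHs()

    for b in rd.GetBonds():
        if b.GetIsAromatic() or b.GetBondType() == Chem.BondType.AROMATIC:
            continue
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        sym = rd.GetAtomWithIdx(i).GetSymbol() + rd.GetAtomWithIdx(j).GetSymbol()
        out["DeleteBond"].append(SSREdit("DeleteBond", bond_sites=(i, j), bond_symbol=sym))
        order = b.GetBondTypeAsDouble()
        for new_order, tok in _ORDER_TOKENS.items():
            if new_order == order:
                continue
            delta = new_order - order
            if delta > 0 and (hs(i) < delta or hs(j) < delta):
                continue
            out["ChangeBond"].append(
                SSREdit("ChangeBond", bond_sites=(i, j), bond_symbol=sym, new_bond_order=tok)
            )
        # LeaveGroup: excise the smaller side of an acyclic single bond
        if not b.IsInRing() and b.GetBondType() == Chem.BondType.SINGLE:
            for inner, outer in ((i, j), (j, i)):
                comp = _side_of(rd, inner, outer)
                if 1 <= len(comp) <= rd.GetNumAtoms() - 2:
                    out["LeaveGroup"].append(
                        SSREdit("LeaveGroup", group_smiles=_LEAVE_SENTINEL + f"{inner}.{outer}")
                    )
    # AddBond between distant atoms with spare valence
    from rdkit.Chem import rdmolops

    dm = rdmolops.GetDistanceMatrix(rd)
    n = rd.GetNumAtoms()
    for i in range(n):
        for j in range(i + 1, n):
            if 2 <= dm[i][j] <= 6 and hs(i) >= 1 and hs(j) >= 1:
                if rd.GetAtomWithIdx(i).GetIsAromatic() or rd.GetAtomWithIdx(j).GetIsAromatic():
                    continue
                sym = rd.GetAtomWithIdx(i).GetSymbol() + rd.GetAtomWithIdx(j).GetSymbol()
                out["AddBond"].append(
                    SSREdit("AddBond", bond_sites=(i, j), bond_symbol=sym, new_bond_order="-")
                )
    for a in rd.GetAtoms():
        idx = a.GetIdx()
        if a.GetTotalNumHs() >= 1 and not a.GetIsAromatic():
            grp = pool[int(rng.integers(0, len(pool)))]
            out["AttachGroup"].append(SSREdit("AttachGroup", group_smiles=grp, site=idx))
        key = (a.GetSymbol(), a.GetFormalCharge())
        if key in _CHARGE_TOGGLE:
            desc = _CHARGE_TOGGLE[key]
            if not (desc in ("N+",) and a.GetTotalValence() >= 4):
                out["ChangeAtom"].append(SSREdit("ChangeAtom", atom_symbol=desc, site=idx))
    return out


_LEAVE_SENTINEL = "*@@leave@@"  # placeholder operand; realized lazily


def _side_of(rd: Chem.Mol, keep: int, cut: int) -> list[int]:
    """Atoms on the ``cut`` side of the keep-cut bond (the leaving side)."""
    seen = {keep, cut}
    stack = [cut]
    comp = [cut]
    while stack:
        u = stack.pop()
        for nb in rd.GetAtomWithIdx(u).GetNeighbors():
            v = nb.GetIdx()
            if v not in seen:
                seen.add(v)
                stack.append(v)
                comp.append(v)
    return comp


def _realize_leave(mol: IndexedMolecule, edit: SSREdit) -> SSREdit:
    """Turn a leave-site placeholder into a concrete group operand."""
    from .ssredits import _fragment_smiles  # shared fragment writer

    inner, outer = map(int, edit.group_smiles[len(_LEAVE_SENTINEL):].split("."))
    comp = _side_of(mol.rdmol, inner, outer)
    group = _fragment_smiles(mol.rdmol, sorted(comp), [(outer, inner)])
    return SSREdit("LeaveGroup", group_smiles=group)


def random_edit(mol: IndexedMolecule, rng) -> SSREdit:
    """Draw one chemically applicable structural edit, uniformly over the
    applicable action types then over valid sites/operands."""
    rng, _ = _as_rng(rng)
    cands = _candidate_edits(mol, rng)
    for _ in range(20):
        types = [t for t, lst in cands.items() if lst]
        if not types:
            break
        t = types[int(rng.integers(0, len(types)))]
        lst = cands[t]
        edit = lst[int(rng.integers(0, len(lst)))]
        if t == "LeaveGroup":
            try:
                edit = _realize_leave(mol, edit)
            except ScriptError:
                lst.remove(edit)
                continue
        try:
            apply_edits(mol, SSREditScript((edit, SSREdit("Terminate"))))
            return edit
        except ScriptError:
            try:
                lst.remove(edit)
            except ValueError:
                pass
    raise SkipExample(f"no applicable edit on {mol.smiles()}")


def _draw_edit_pair(smiles: str, rng: np.random.Generator) -> tuple[str, SSREditScript, str]:
    """Shared draw for MakeSSREdits / MakeSMILES: (orig, script, edited)."""
    mol = parse_molecule(smiles)
    if mol.rdmol.GetNumBonds() < 1:
        raise SkipExample("molecule has no bonds")
    edit = random_edit(mol, rng)
    script = SSREditScript((edit, SSREdit("Terminate")))
    try:
        components = apply_edits(mol, script)
    except ScriptError as exc:  # pragma: no cover - random_edit pre-validates
        raise SkipExample(str(exc)) from exc
    edited = ".".join(sorted(m.smiles() for m in components))
    return mol.smiles(), script, edited


def make_ssredits_example(smiles: str, rng) -> TrainingExample:
    """Input ``orig>>edited``; target: the edit script that caused it."""
    rng, seed = _as_rng(rng)
    orig, script, edited = _draw_edit_pair(smiles, rng)
    inp = tuple(tokenize_smiles(orig)) + (">>",) + tuple(tokenize_smiles(edited))
    tgt = tuple(serialize_script(script))
    return TrainingExample("MakeSSREdits", TokenSequence(inp), TokenSequence(tgt), seed)


def make_smiles_example(smiles: str, rng) -> TrainingExample:
    """Input ``orig [SEP] script``; target: the edited SMILES."""
    rng, seed = _as_rng(rng)
    orig, script, edited = _draw_edit_pair(smiles, rng)
    inp = tuple(tokenize_smiles(orig)) + (SEP,) + tuple(serialize_script(script))
    tgt = tuple(tokenize_smiles(edited))
    return TrainingExample("MakeSMILES", TokenSequence(inp), TokenSequence(tgt), seed)


_BUILDERS = {
    "FillMASK": fillmask_example,
    "MakeSSREdits": make_ssredits_example,
    "MakeSMILES": make_smiles_example,
}


def build_corpus(
    smiles_file: "str | Path | list[str]",
    task: str,
    n: int,
    seed: int,
    out: Optional[Path] = None,
) -> list[TrainingExample]:
    """Draw exactly ``n`` examples for ``task``, skipping unusable inputs.

    Deterministic: attempt ``k`` uses the input line ``k mod len(lines)``
    and its own derived seed, so the same call is byte-reproducible.
    """
    if task not in _BUILDERS:
        raise ValueError(f"unknown corpus task {task!r} (choose from {sorted(_BUILDERS)})")
    if isinstance(smiles_file, (str, Path)):
        try:
            lines = [
                ln.strip()
                for ln in Path(smiles_file).read_text().splitlines()
                if ln.strip()
            ]
        except OSError as exc:
            raise IOError(f"cannot read SMILES file {smiles_file}: {exc}") from exc
    else:
        lines = [str(s) for s in smiles_file]
    if not lines:
        raise IOError("empty SMILES input")
    builder = _BUILDERS[task]
    examples: list[TrainingExample] = []
    skipped = 0
    max_attempts = max(50 * n, 1000)
    for k in range(max_attempts):
        if len(examples) >= n:
            break
        smi = lines[k % len(lines)]
        ex_seed = (seed * 1_000_003 + k) % (2**31)
        try:
            ex = builder(smi, ex_seed)
        except (SkipExample, ScriptError, ValueError):
            skipped += 1
            continue
        examples.append(ex)
    if len(examples) < n:
        raise IOError(
            f"input pool exhausted: produced {len(examples)}/{n} examples "
            f"({skipped} skipped)"
        )
    if out is not None:
        Path(out).write_text("".join(ex.to_json() + "\n" for ex in examples))
    return examples
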