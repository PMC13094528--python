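"""Site-specific reaction edit (SSREdit) codec.

A retrosynthetic step is encoded as an ordered script of typed edit
actions addressed to the product's canonical atom IDs:

* ``[Delete][Bond]``, ``[Change][Bond]``, ``[Add][Bond]`` — bond surgery
  between two numbered atoms;
* ``[Attach][Group]`` / ``[Leave][Group]`` — splice in / excise a
  wildcard-anchored substructure;
* ``[Change][Atom]`` — retarget an atom's charge / stereocenter;
* ``[Terminate]`` — close the script and repair implicit hydrogens so
  every atom satisfies standard valence;
* ``[EC]`` — annotate the script with the Enzyme Commission number of the
  catalyzing enzyme.

The codec is lossless in the round-trip sense: ``apply_edits(product,
extract_edits(rxn))`` reproduces the reactant set of an atom-mapped
reaction up to canonical SMILES.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from rdkit import Chem

from .chemgraph import (
    IndexedMolecule,
    MoleculeError,
    Reaction,
    TokenSequence,
    canonical_smiles,
)
from .enzyme_eval import ECNumber

__all__ = [
    "SSREdit",
    "SSREditScript",
    "ScriptError",
    "ScriptParseError",
    "ApplicationError",
    "ValidityError",
    "ExtractionError",
    "extract_edits",
    "apply_edits",
    "apply_edits_tracked",
    "serialize_script",
    "script_text",
    "parse_script",
]

ACTIONS = (
    "DeleteBond",
    "ChangeBond",
    "AddBond",
    "AttachGroup",
    "LeaveGroup",
    "ChangeAtom",
    "Terminate",
    "EC",
)

#: canonical emission order of structural phases during extraction
PHASE_ORDER = {
    "DeleteBond": 0,
    "ChangeBond": 1,
    "AddBond": 2,
    "LeaveGroup": 3,
    "AttachGroup": 4,
    "ChangeAtom": 5,
    "Terminate": 6,
    "EC": 7,
}

_ORDER_TOKEN = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}
_TOKEN_ORDER = {v: k for k, v in _ORDER_TOKEN.items()}

_DESCRIPTOR_RE = re.compile(r"^([A-Z][a-z]?)([+-]\d*)?(?:@(R|S|0))?$")


class ScriptError(ValueError):
    """Base class for codec failures."""


class ScriptParseError(ScriptError):
    """Token sequence does not conform to the edit grammar."""


class ApplicationError(ScriptError):
    """Script references an atom or bond missing from the evolving graph."""


class ValidityError(ScriptError):
    """Hydrogen repair cannot satisfy standard valence — the script is
    chemically infeasible (used to filter generated beam candidates)."""


class ExtractionError(ScriptError):
    """Atom-mapped reaction cannot be expressed in the edit grammar."""


@dataclass(frozen=True)
class SSREdit:
    """One typed edit action with exactly the operands its action needs."""

    action: str
    bond_sites: Optional[tuple[int, int]] = None
    bond_symbol: Optional[str] = None
    new_bond_order: Optional[str] = None
    group_smiles: Optional[str] = None
    site: Optional[int] = None
    atom_symbol: Optional[str] = None
    ec: Optional[ECNumber] = None

    def __post_init__(self):
        if self.action not in ACTIONS:
            raise ScriptError(f"unknown action {self.action!r}")
        need_bond = self.action in ("DeleteBond", "ChangeBond", "AddBond")
        if need_bond:
            if self.bond_sites is None or self.bond_symbol is None:
                raise ScriptError(f"{self.action} requires bond_sites and bond_symbol")
            i, j = self.bond_sites
            if i == j:
                raise ScriptError("bond_sites must be distinct atom ids")
            if self.action != "DeleteBond" and self.new_bond_order not in _TOKEN_ORDER:
                raise ScriptError(f"{self.action} requires a bond order token")
        if self.action == "AttachGroup":
            if self.group_smiles is None or self.site is None:
                raise ScriptError("AttachGroup requires group_smiles and site")
        if self.action == "LeaveGroup" and self.group_smiles is None:
            raise ScriptError("LeaveGroup requires group_smiles")
        if self.action in ("AttachGroup", "LeaveGroup") and "*" not in self.group_smiles:
            raise ScriptError("group_smiles must contain a wildcard attachment atom")
        if self.action == "ChangeAtom":
            if self.atom_symbol is None or self.site is None:
                raise ScriptError("ChangeAtom requires atom_symbol and site")
            if not _DESCRIPTOR_RE.match(self.atom_symbol):
                raise ScriptError(f"bad ChangeAtom descriptor {self.atom_symbol!r}")
        if self.action == "EC" and self.ec is None:
            raise ScriptError("EC action requires an ECNumber")


@dataclass(frozen=True)
class SSREditScript:
    """Ordered edits: structural actions, one Terminate, optional EC."""

    edits: tuple[SSREdit, ...]

    def __post_init__(self):
        terms = [k for k, e in enumerate(self.edits) if e.action == "Terminate"]
        if len(terms) != 1:
            raise ScriptError("script must contain exactly one Terminate")
        t = terms[0]
        tail = self.edits[t + 1 :]
        if any(e.action != "EC" for e in tail) or len(tail) > 1:
            raise ScriptError("only a single EC action may follow Terminate")
        if any(e.action == "EC" for e in self.edits[:t]):
            raise ScriptError("EC action must be last")

    @property
    def structural(self) -> tuple[SSREdit, ...]:
        return tuple(e for e in self.edits if e.action not in ("Terminate", "EC"))

    @property
    def annotated_ec(self) -> Optional[ECNumber]:
        for e in self.edits:
            if e.action == "EC":
                return e.ec
        return None

    def __len__(self):
        return len(self.edits)


def _bond_symbol(mol: Chem.Mol, i: int, j: int) -> str:
    a, b = sorted((i, j))
    return mol.GetAtomWithIdx(a).GetSymbol() + mol.GetAtomWithIdx(b).GetSymbol()


# ---------------------------------------------------------------------------
# serialization


def _edit_fields(e: SSREdit) -> list[str]:
    if e.action in ("DeleteBond", "ChangeBond", "AddBond"):
        i, j = sorted(e.bond_sites)
        verb = {"DeleteBond": "Delete", "ChangeBond": "Change", "AddBond": "Add"}[e.action]
        fields = [f"[{verb}][Bond]{e.bond_symbol}:", f"{i}.{j}"]
        if e.action != "DeleteBond":
            fields.append(e.new_bond_order)
        return fields
    if e.action == "AttachGroup":
        return [f"[Attach][Group]{e.group_smiles}:", str(e.site)]
    if e.action == "LeaveGroup":
        return [f"[Leave][Group]{e.group_smiles}"]
    if e.action == "ChangeAtom":
        return [f"[Change][Atom]{e.atom_symbol}:", str(e.site)]
    if e.action == "Terminate":
        return ["[Terminate]"]
    if e.action == "EC":
        return ["[EC]"] + ["-" if f is None else str(f) for f in e.ec.fields]
    raise ScriptError(e.action)  # pragma: no cover


def serialize_script(script: SSREditScript) -> TokenSequence:
    """Emit the whitespace-delimited token grammar for a valid script."""
    tokens: list[str] = []
    for e in script.edits:
        tokens.extend(_edit_fields(e))
    return TokenSequence(tuple(tokens))


def script_text(script: SSREditScript) -> str:
    """The printed form, e.g. ``[Delete][Bond]CN: 7.8 [Terminate]``."""
    return " ".join(serialize_script(script))


_BOND_HEAD_RE = re.compile(r"^\[(Delete|Change|Add)\]\[Bond\](.+):$")
_SITES_RE = re.compile(r"^(\d+)\.(\d+)$")


def parse_script(tokens: "TokenSequence | Sequence[str] | str") -> SSREditScript:
    """Invert :func:`serialize_script`; total over whitespace-split text."""
    if isinstance(tokens, str):
        fields = tokens.split()
    else:
        fields = " ".join(tokens).split()
    edits: list[SSREdit] = []
    pos = 0

    def take(what: str) -> str:
        nonlocal pos
        if pos >= len(fields):
            raise ScriptParseError(f"unexpected end of script, expected {what} at token {pos}")
        f = fields[pos]
        pos += 1
        return f

    def take_sites(head: str) -> tuple[int, int]:
        f = take("atom-site pair i.j")
        m = _SITES_RE.match(f)
        if not m:
            raise ScriptParseError(f"token {pos - 1}: bad site pair {f!r} after {head!r}")
        return int(m.group(1)), int(m.group(2))

    while pos < len(fields):
        head = fields[pos]
        mb = _BOND_HEAD_RE.match(head)
        if mb:
            pos += 1
            verb, sym = mb.group(1), mb.group(2)
            sites = take_sites(head)
            if verb == "Delete":
                edits.append(SSREdit("DeleteBond", bond_sites=sites, bond_symbol=sym))
            else:
                order = take("bond-order token")
                if order not in _TOKEN_ORDER:
                    raise ScriptParseError(f"token {pos - 1}: bad bond order {order!r}")
                edits.append(
                    SSREdit(
                        "ChangeBond" if verb == "Change" else "AddBond",
                        bond_sites=sites,
                        bond_symbol=sym,
                        new_bond_order=order,
                    )
                )
        elif head.startswith("[Attach][Group]") and head.endswith(":"):
            pos += 1
            group = head[len("[Attach][Group]") : -1]
            site = take("attachment site")
            if not site.isdigit():
                raise ScriptParseError(f"token {pos - 1}: bad attach site {site!r}")
            edits.append(SSREdit("AttachGroup", group_smiles=group, site=int(site)))
        elif head.startswith("[Leave][Group]"):
            pos += 1
            edits.append(SSREdit("LeaveGroup", group_smiles=head[len("[Leave][Group]") :]))
        elif head.startswith("[Change][Atom]") and head.endswith(":"):
            pos += 1
            desc = head[len("[Change][Atom]") : -1]
            site = take("atom site")
            if not site.isdigit():
                raise ScriptParseError(f"token {pos - 1}: bad atom site {site!r}")
            edits.append(SSREdit("ChangeAtom", atom_symbol=desc, site=int(site)))
        elif head == "[Terminate]":
            pos += 1
            edits.append(SSREdit("Terminate"))
        elif head == "[EC]":
            pos += 1
            vals = []
            for _ in range(4):
                f = take("EC field")
                if f == "-":
                    vals.append(None)
                elif f.isdigit():
                    vals.append(int(f))
                else:
                    raise ScriptParseError(f"token {pos - 1}: bad EC field {f!r}")
            edits.append(SSREdit("EC", ec=ECNumber(tuple(vals))))
        else:
            raise ScriptParseError(f"token {pos}: unrecognized action {head!r}")
    if not any(e.action == "Terminate" for e in edits):
        raise ScriptParseError("incomplete script: missing [Terminate]")
    try:
        return SSREditScript(tuple(edits))
    except ScriptError as exc:
        raise ScriptParseError(str(exc)) from exc


# ---------------------------------------------------------------------------
# application

_ADJ = Chem.AdjustQueryParameters.NoAdjustments()
_ADJ.makeDummiesQueries = True


def _group_query(group_smiles: str) -> Chem.Mol:
    g = Chem.MolFromSmiles(group_smiles)
    if g is None:
        raise ApplicationError(f"unparsable group operand {group_smiles!r}")
    return g


def _idx_of(rw: Chem.RWMol, pid: int) -> int:
    for a in rw.GetAtoms():
        if a.GetAtomMapNum() == pid + 1:
            return a.GetIdx()
    raise ApplicationError(f"atom id {pid} not present in the evolving graph")


def _repair_hydrogens(mol: Chem.Mol, touched_idx: set[int]) -> Chem.Mol:
    """Zero out H bookkeeping on touched atoms and re-derive it by valence."""
    for idx in touched_idx:
        a = mol.GetAtomWithIdx(idx)
        a.SetNumExplicitHs(0)
        a.SetNoImplicit(False)
    try:
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        pass
    # aromatic nitrogens sometimes need one explicit H to kekulize
    retry = Chem.Mol(mol)
    for idx in touched_idx:
        a = retry.GetAtomWithIdx(idx)
        if a.GetSymbol() == "N" and a.GetIsAromatic() and a.GetDegree() == 2:
            a.SetNumExplicitHs(1)
    try:
        Chem.SanitizeMol(retry)
        return retry
    except Exception as exc:
        raise ValidityError(f"hydrogen repair failed: {exc}") from exc


def _sanitized_snapshot(rw: Chem.RWMol, touched: set[int]) -> Chem.Mol:
    cp = Chem.Mol(rw)
    idxs = set()
    for a in cp.GetAtoms():
        if a.GetAtomMapNum() and a.GetAtomMapNum() - 1 in touched:
            idxs.add(a.GetIdx())
    return _repair_hydrogens(cp, idxs)


def _set_target_cip(rw: Chem.RWMol, pid: int, code: str, touched: set[int]) -> None:
    idx = _idx_of(rw, pid)
    if code == "0":
        rw.GetAtomWithIdx(idx).SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
        return
    for tag in (Chem.ChiralType.CHI_TETRAHEDRAL_CW, Chem.ChiralType.CHI_TETRAHEDRAL_CCW):
        rw.GetAtomWithIdx(idx).SetChiralTag(tag)
        try:
            cp = _sanitized_snapshot(rw, touched)
        except ValidityError:
            continue
        Chem.AssignStereochemistry(cp, cleanIt=True, force=True)
        a = cp.GetAtomWithIdx(idx)
        if a.HasProp("_CIPCode") and a.GetProp("_CIPCode") == code:
            return
    raise ApplicationError(f"cannot realize CIP code {code} at atom {pid}")


def _leave_group(
    rw: Chem.RWMol, group: str, touched: set[int], protected: set[int] = frozenset()
) -> None:
    """Excise the first valid match of a wildcard-anchored group.

    A match is valid when every bond out of the removable atoms passes
    through a wildcard anchor.  The operand carries no atom site, so among
    valid matches the first (in sorted atom order) that does not remove an
    atom a later edit still addresses is preferred — this resolves the
    ambiguity of symmetric molecules deterministically.
    """
    query = Chem.AdjustQueryProperties(_group_query(group), _ADJ)
    wild_q = {a.GetIdx() for a in query.GetAtoms() if a.GetAtomicNum() == 0}
    target = rw.GetMol()
    valid: list[tuple[set[int], set[int]]] = []
    for match in sorted(target.GetSubstructMatches(query, uniquify=True)):
        anchors = {match[q] for q in wild_q}
        removable = {match[q] for q in range(query.GetNumAtoms()) if q not in wild_q}
        ok = True
        for idx in removable:
            for nb in target.GetAtomWithIdx(idx).GetNeighbors():
                k = nb.GetIdx()
                if k not in removable and k not in anchors:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            valid.append((anchors, removable))
    if not valid:
        raise ApplicationError(f"leave-group {group!r} has no removable match")
    chosen = None
    for anchors, removable in valid:
        pids = {
            target.GetAtomWithIdx(idx).GetAtomMapNum() - 1
            for idx in removable
            if target.GetAtomWithIdx(idx).GetAtomMapNum()
        }
        if not (pids & protected):
            chosen = (anchors, removable)
            break
    if chosen is None:
        chosen = valid[0]
    anchors, removable = chosen
    for idx in anchors:
        num = rw.GetAtomWithIdx(idx).GetAtomMapNum()
        if num:
            touched.add(num - 1)
    for idx in sorted(removable, reverse=True):
        rw.RemoveAtom(idx)


def _attach_group(rw: Chem.RWMol, group: str, site: int, touched: set[int]) -> None:
    frag = _group_query(group)
    wilds = [a.GetIdx() for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
    if len(wilds) != 1:
        raise ApplicationError(
            f"attach-group operand must carry exactly one wildcard: {group!r}"
        )
    w = wilds[0]
    wild_atom = frag.GetAtomWithIdx(w)
    site_idx = _idx_of(rw, site)
    offset = rw.GetNumAtoms()
    rw.InsertMol(frag)
    if wild_atom.GetDegree() == 1:
        bond = frag.GetBonds()[0] if frag.GetNumBonds() == 1 else None
        nb = wild_atom.GetNeighbors()[0].GetIdx()
        order = frag.GetBondBetweenAtoms(w, nb).GetBondType()
        rw.AddBond(site_idx, offset + nb, order)
    elif wild_atom.GetDegree() != 0:
        raise ApplicationError(f"wildcard in {group!r} must have degree 0 or 1")
    # degree 0: dot-disconnected operand — the fragment arrives as a free
    # component (cofactor-style reactant); the site only records the anchor.
    rw.RemoveAtom(offset + w)
    touched.add(site)


def apply_edits_tracked(
    product: IndexedMolecule, script: SSREditScript
) -> tuple[list[IndexedMolecule], dict[int, tuple[int, int]]]:
    """Apply a script; also return the surviving-atom map.

    Returns ``(components, id_map)`` with ``id_map[product_atom_id] =
    (component_index, component_atom_id)`` for every product atom that
    persists — exactly the atom map of the reaction the script encodes.
    """
    rw = Chem.RWMol(product.rdmol)
    for a in rw.GetAtoms():
        a.SetAtomMapNum(a.GetIdx() + 1)
    touched: set[int] = set()
    terminated = False
    for pos, e in enumerate(script.edits):
        if e.action == "EC":
            continue
        if terminated:
            raise ApplicationError("structural edit after [Terminate]")
        if e.action == "DeleteBond":
            i, j = (_idx_of(rw, p) for p in e.bond_sites)
            b = rw.GetBondBetweenAtoms(i, j)
            if b is None:
                raise ApplicationError(f"no bond between atoms {e.bond_sites}")
            if b.GetIsAromatic():
                # explicit orders are needed before ring surgery; aromaticity
                # is re-perceived at Terminate
                Chem.Kekulize(rw, clearAromaticFlags=True)
            rw.RemoveBond(i, j)
            touched.update(e.bond_sites)
        elif e.action == "ChangeBond":
            i, j = (_idx_of(rw, p) for p in e.bond_sites)
            b = rw.GetBondBetweenAtoms(i, j)
            if b is None:
                raise ApplicationError(f"no bond between atoms {e.bond_sites}")
            if b.GetIsAromatic():
                Chem.Kekulize(rw, clearAromaticFlags=True)
                b = rw.GetBondBetweenAtoms(i, j)
            b.SetBondType(_TOKEN_ORDER[e.new_bond_order])
            b.SetIsAromatic(False)
            touched.update(e.bond_sites)
        elif e.action == "AddBond":
            i, j = (_idx_of(rw, p) for p in e.bond_sites)
            if rw.GetBondBetweenAtoms(i, j) is not None:
                raise ApplicationError(f"bond already present between {e.bond_sites}")
            rw.AddBond(i, j, _TOKEN_ORDER[e.new_bond_order])
            touched.update(e.bond_sites)
        elif e.action == "LeaveGroup":
            protected: set[int] = set()
            for later in script.edits[pos + 1 :]:
                if later.bond_sites:
                    protected.update(later.bond_sites)
                if later.site is not None:
                    protected.add(later.site)
            _leave_group(rw, e.group_smiles, touched, protected)
        elif e.action == "AttachGroup":
            _attach_group(rw, e.group_smiles, e.site, touched)
        elif e.action == "ChangeAtom":
            m = _DESCRIPTOR_RE.match(e.atom_symbol)
            sym, charge, stereo = m.group(1), m.group(2), m.group(3)
            idx = _idx_of(rw, e.site)
            a = rw.GetAtomWithIdx(idx)
            pt = Chem.GetPeriodicTable()
            new_z = pt.GetAtomicNumber(sym)
            if new_z != a.GetAtomicNum():
                a.SetAtomicNum(new_z)
            if charge is None:
                a.SetFormalCharge(0)
            elif charge in ("+", "-"):
                a.SetFormalCharge(1 if charge == "+" else -1)
            else:
                a.SetFormalCharge(int(charge))
            touched.add(e.site)
            if stereo is not None:
                _set_target_cip(rw, e.site, stereo, touched)
        elif e.action == "Terminate":
            terminated = True
    mol = rw.GetMol()
    touched_idx = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomMapNum() and a.GetAtomMapNum() - 1 in touched
    }
    mol = _repair_hydrogens(mol, touched_idx)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)

    components: list[IndexedMolecule] = []
    id_map: dict[int, tuple[int, int]] = {}
    for fi, frag in enumerate(Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)):
        mapnums = [a.GetAtomMapNum() for a in frag.GetAtoms()]
        for a in frag.GetAtoms():
            a.SetAtomMapNum(0)
        try:
            Chem.SanitizeMol(frag)
        except Exception as exc:
            raise ValidityError(f"invalid component after edits: {exc}") from exc
        ranks = list(Chem.CanonicalRankAtoms(frag, breakTies=True))
        inverse = [0] * len(ranks)
        for idx, r in enumerate(ranks):
            inverse[r] = idx
        renum = Chem.RenumberAtoms(frag, inverse)
        components.append(IndexedMolecule(rdmol=renum, source_smiles=Chem.MolToSmiles(renum)))
        for old_idx, num in enumerate(mapnums):
            if num:
                id_map[num - 1] = (fi, ranks[old_idx])
    return components, id_map


def apply_edits(product: IndexedMolecule, script: SSREditScript) -> list[IndexedMolecule]:
    """Materialize the reactant set a script encodes, as valid components."""
    return apply_edits_tracked(product, script)[0]


# ---------------------------------------------------------------------------
# extraction


def _cip_codes(mol: Chem.Mol) -> dict[int, str]:
    cp = Chem.Mol(mol)
    Chem.AssignStereochemistry(cp, cleanIt=True, force=True)
    return {
        a.GetIdx(): a.GetProp("_CIPCode")
        for a in cp.GetAtoms()
        if a.HasProp("_CIPCode")
    }


def _unmapped_components(mol: Chem.Mol, unmapped: set[int]) -> list[list[int]]:
    seen: set[int] = set()
    comps = []
    for start in sorted(unmapped):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for nb in mol.GetAtomWithIdx(u).GetNeighbors():
                v = nb.GetIdx()
                if v in unmapped and v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _fragment_smiles(mol: Chem.Mol, comp: list[int], boundary: list[tuple[int, int]]) -> str:
    """SMILES of ``comp`` with one wildcard per boundary bond, wildcard-rooted.

    Delegates the cut to RDKit bond fragmentation so stereocenters inside
    the fragment keep their parity.
    """
    bond_ids = []
    for inner, outer in boundary:
        b = mol.GetBondBetweenAtoms(inner, outer)
        if b.GetIdx() not in bond_ids:
            bond_ids.append(b.GetIdx())
    work = Chem.Mol(mol)
    for a in work.GetAtoms():
        a.SetAtomMapNum(0)
    try:
        fragged = Chem.FragmentOnBonds(work, bond_ids, addDummies=True)
    except Exception as exc:
        raise ExtractionError(f"cannot cut group fragment: {exc}") from exc
    comp_set = set(comp)
    for piece_idx, piece in zip(
        Chem.GetMolFrags(fragged), Chem.GetMolFrags(fragged, asMols=True, sanitizeFrags=False)
    ):
        if comp_set & set(piece_idx):
            frag = piece
            break
    else:  # pragma: no cover
        raise ExtractionError("fragment bookkeeping failure")
    for a in frag.GetAtoms():
        a.SetIsotope(0)  # FragmentOnBonds labels dummies with the cut site
    try:
        Chem.SanitizeMol(frag)
    except Exception as exc:
        raise ExtractionError(f"group fragment not independently valid: {exc}") from exc
    wild = [a.GetIdx() for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
    ranks = list(Chem.CanonicalRankAtoms(frag, breakTies=True))
    root = min(wild, key=lambda w: ranks[w])
    return Chem.MolToSmiles(frag, rootedAtAtom=root, canonical=True)


def extract_edits(reaction: Reaction) -> SSREditScript:
    """Diff an atom-mapped reaction into its canonical edit script.

    Edits are emitted in a fixed phase order (bond deletions, bond-order
    changes, bond additions, leaving groups, attaching groups, atom
    changes), each phase sorted by atom site, so the learning target for a
    given transformation is unambiguous.
    """
    P = reaction.product.rdmol
    amap = reaction.atom_map
    mapped = set(amap)
    edits: list[SSREdit] = []

    # Kekulized reactant views: when aromaticity appears or vanishes across
    # the reaction, edits must carry explicit single/double orders — the
    # hydrogen-repair sanitization re-perceives aromaticity after apply.
    kek_reactants = []
    for r in reaction.reactants:
        kek = Chem.Mol(r.rdmol)
        try:
            Chem.Kekulize(kek, clearAromaticFlags=True)
        except Exception:
            kek = r.rdmol
        kek_reactants.append(kek)

    def reactant_order_token(ri: int, rai: int, raj: int) -> str:
        rb = reaction.reactants[ri].rdmol.GetBondBetweenAtoms(rai, raj)
        bt = rb.GetBondType()
        if bt == Chem.BondType.AROMATIC:
            bt = kek_reactants[ri].GetBondBetweenAtoms(rai, raj).GetBondType()
        tok = _ORDER_TOKEN.get(bt)
        if tok is None:
            raise ExtractionError(f"unsupported reactant bond type {bt}")
        return tok

    # --- bond phases over mapped atom pairs
    for b in P.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        if i not in mapped or j not in mapped:
            continue
        (ri, rai), (rj, raj) = amap[i], amap[j]
        sym = _bond_symbol(P, i, j)
        if ri != rj:
            edits.append(SSREdit("DeleteBond", bond_sites=(i, j), bond_symbol=sym))
            continue
        rb = reaction.reactants[ri].rdmol.GetBondBetweenAtoms(rai, raj)
        if rb is None:
            edits.append(SSREdit("DeleteBond", bond_sites=(i, j), bond_symbol=sym))
        elif rb.GetBondType() != b.GetBondType():
            edits.append(
                SSREdit(
                    "ChangeBond",
                    bond_sites=(i, j),
                    bond_symbol=sym,
                    new_bond_order=reactant_order_token(ri, rai, raj),
                )
            )
    rev = {v: k for k, v in amap.items()}
    for ri, rmol in enumerate(reaction.reactants):
        for b in rmol.rdmol.GetBonds():
            u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if (ri, u) in rev and (ri, v) in rev:
                p, q = sorted((rev[(ri, u)], rev[(ri, v)]))
                if P.GetBondBetweenAtoms(p, q) is None:
                    edits.append(
                        SSREdit(
                            "AddBond",
                            bond_sites=(p, q),
                            bond_symbol=_bond_symbol(P, p, q),
                            new_bond_order=reactant_order_token(ri, u, v),
                        )
                    )

    # --- leaving groups: product substructures with no mapped image
    unmapped_p = set(range(P.GetNumAtoms())) - mapped
    leave: list[SSREdit] = []
    for comp in _unmapped_components(P, unmapped_p):
        boundary = []
        comp_set = set(comp)
        for idx in comp:
            for nb in P.GetAtomWithIdx(idx).GetNeighbors():
                if nb.GetIdx() not in comp_set:
                    boundary.append((idx, nb.GetIdx()))
        group = _fragment_smiles(P, comp, sorted(boundary, key=lambda t: t[1]))
        leave.append(SSREdit("LeaveGroup", group_smiles=group))
    edits.extend(sorted(leave, key=lambda e: e.group_smiles))

    # --- attaching groups: unmapped reactant substructures
    attach: list[SSREdit] = []
    for ri, rmol in enumerate(reaction.reactants):
        R = rmol.rdmol
        mapped_r = {rai for (rj, rai) in rev if rj == ri}
        unmapped_r = set(range(R.GetNumAtoms())) - mapped_r
        for comp in _unmapped_components(R, unmapped_r):
            comp_set = set(comp)
            boundary = []
            for idx in comp:
                for nb in R.GetAtomWithIdx(idx).GetNeighbors():
                    if nb.GetIdx() not in comp_set:
                        boundary.append((idx, nb.GetIdx()))
            if len(boundary) > 1:
                raise ExtractionError(
                    "reactant fragment bonded to multiple mapped atoms is not "
                    "expressible as a single-site attach group"
                )
            if boundary:
                inner, outer = boundary[0]
                site = rev[(ri, outer)]
                group = _fragment_smiles(R, comp, [boundary[0]])
            elif len(comp) == R.GetNumAtoms():
                # wholly unmapped reactant (free cofactor): dot-disconnected
                # wildcard operand; the anchor site is informational only.
                site = min(mapped) if mapped else 0
                group = "*." + canonical_smiles(rmol)
            else:  # pragma: no cover - disconnected reactant SMILES part
                raise ExtractionError("unmapped reactant fragment with no anchor")
            attach.append(SSREdit("AttachGroup", group_smiles=group, site=site))
    edits.extend(sorted(attach, key=lambda e: (e.site, e.group_smiles)))

    # --- atom changes: charge / CIP stereocenter retargeting
    prod_cip = _cip_codes(P)
    react_cip = [_cip_codes(r.rdmol) for r in reaction.reactants]
    atom_edits: list[SSREdit] = []
    for pid in sorted(mapped):
        ri, rai = amap[pid]
        pa = P.GetAtomWithIdx(pid)
        ra = reaction.reactants[ri].rdmol.GetAtomWithIdx(rai)
        charge_differs = pa.GetFormalCharge() != ra.GetFormalCharge()
        p_code = prod_cip.get(pid)
        r_code = react_cip[ri].get(rai)
        stereo = None
        if p_code != r_code:
            stereo = r_code if r_code is not None else "0"
        if charge_differs or stereo is not None:
            desc = ra.GetSymbol()
            c = ra.GetFormalCharge()
            if c == 1:
                desc += "+"
            elif c == -1:
                desc += "-"
            elif c != 0:
                desc += f"{c:+d}"
            if stereo is not None:
                desc += f"@{stereo}"
            atom_edits.append(SSREdit("ChangeAtom", atom_symbol=desc, site=pid))
    edits.extend(atom_edits)

    edits.append(SSREdit("Terminate"))
    if reaction.ec is not None:
        edits.append(SSREdit("EC", ec=reaction.ec))
    return SSREditScript(tuple(edits))
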