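"""Molecule and reaction data model.

Every site-specific edit is addressed to integer atom IDs, so the whole
toolkit hinges on one convention: heavy atoms of a parsed molecule are
numbered 0..n-1 in RDKit canonical-rank order.  Parsing the same structure
from any SMILES spelling therefore yields the same ID for the same atom,
which makes edit scripts portable across spellings and makes extraction
deterministic.

Hydrogens never receive IDs; they are implicit and repaired by valence
rules when a script terminates (see :mod:`enzedit.ssredits`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeError",
    "IndexedMolecule",
    "Reaction",
    "TokenSequence",
    "parse_molecule",
    "parse_reaction",
    "tokenize_smiles",
    "canonical_smiles",
    "tanimoto_similarity",
    "morgan_bits",
    "FINGERPRINT_RADIUS",
    "FINGERPRINT_BITS",
]

#: Circular (Morgan/ECFP4) fingerprint parameters used for every Tanimoto
#: computation in the package.
FINGERPRINT_RADIUS = 2
FINGERPRINT_BITS = 2048


class MoleculeError(ValueError):
    """Raised for malformed SMILES or chemically invalid molecules."""


# Tokenization follows the scheme standard for SMILES language models:
# bracket atoms, two-letter organic-subset halogens, ring-closure digits
# (incl. %nn), and structural characters are each one token.  The trailing
# catch-all keeps the tokenizer total over arbitrary text.
_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]*\]|Br|Cl|%\d{2}|>>|[BCNOSPFI]|[bcnops]|[()=#\-+\\/:~@?*$.]|\d|.)",
    re.DOTALL,
)


@dataclass(frozen=True)
class TokenSequence:
    """An ordered list of text tokens; joining reproduces the source text."""

    tokens: tuple[str, ...]

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self):
        return len(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    @property
    def text(self) -> str:
        return "".join(self.tokens)


def tokenize_smiles(smiles: str) -> TokenSequence:
    """Split a SMILES string into model tokens, losslessly."""
    return TokenSequence(tuple(_SMILES_TOKEN_RE.findall(smiles)))


def _check_delimiters(smiles: str) -> None:
    """Cheap scan that names the position of unbalanced ()/[] delimiters."""
    stack: list[tuple[str, int]] = []
    pairs = {")": "(", "]": "["}
    for i, ch in enumerate(smiles):
        if ch in "([":
            stack.append((ch, i))
        elif ch in ")]":
            if not stack or stack[-1][0] != pairs[ch]:
                raise MoleculeError(
                    f"SMILES parse error at position {i}: unmatched '{ch}' in {smiles!r}"
                )
            stack.pop()
    if stack:
        ch, i = stack[-1]
        raise MoleculeError(
            f"SMILES parse error at position {i}: unclosed '{ch}' in {smiles!r}"
        )


@dataclass(frozen=True)
class AtomRecord:
    symbol: str
    formal_charge: int
    chirality: str  # "", "@", "@@"
    implicit_h: int
    atom_id: int
    is_attachment: bool = False


_CHI_TO_STR = {
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "@",
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "@@",
}


@dataclass
class IndexedMolecule:
    """A molecule whose heavy atoms carry contiguous canonical IDs.

    Wraps an RDKit mol renumbered so that RDKit atom index == atom_id.
    Wildcard ``*`` atoms are legal, degree-1, and flag attachment points of
    group operands.
    """

    rdmol: Chem.Mol
    source_smiles: str

    @property
    def num_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def atoms(self) -> list[AtomRecord]:
        out = []
        for a in self.rdmol.GetAtoms():
            out.append(
                AtomRecord(
                    symbol=a.GetSymbol(),
                    formal_charge=a.GetFormalCharge(),
                    chirality=_CHI_TO_STR.get(a.GetChiralTag(), ""),
                    implicit_h=a.GetTotalNumHs(),
                    atom_id=a.GetIdx(),
                    is_attachment=a.GetAtomicNum() == 0,
                )
            )
        return out

    @property
    def bonds(self) -> list[tuple[int, int, str]]:
        out = []
        for b in self.rdmol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            out.append((min(i, j), max(i, j), str(b.GetBondType()).lower()))
        return out

    @property
    def attachment_points(self) -> list[int]:
        return [a.GetIdx() for a in self.rdmol.GetAtoms() if a.GetAtomicNum() == 0]

    def smiles(self) -> str:
        return canonical_smiles(self)

    def __repr__(self):  # pragma: no cover
        return f"IndexedMolecule({self.smiles()!r}, n={self.num_atoms})"


def _canonical_renumber(mol: Chem.Mol) -> Chem.Mol:
    """Renumber atoms so atom index i holds the atom of canonical rank i."""
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    inverse = [0] * len(ranks)
    for idx, rank in enumerate(ranks):
        inverse[rank] = idx
    return Chem.RenumberAtoms(mol, inverse)


def parse_molecule(smiles: str) -> IndexedMolecule:
    """Parse SMILES and assign deterministic canonical atom IDs.

    Atom-map annotations (``:n``) are stripped; use :func:`parse_reaction`
    when the mapping is needed.
    """
    if not smiles or not smiles.strip():
        raise MoleculeError("empty SMILES")
    _check_delimiters(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(
            f"SMILES parse error at position 0: cannot parse {smiles!r}"
        )
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    mol = _canonical_renumber(mol)
    return IndexedMolecule(rdmol=mol, source_smiles=smiles)


def mol_from_rdkit(mol: Chem.Mol, source: str = "") -> IndexedMolecule:
    """Wrap a sanitized RDKit mol, renumbering canonically."""
    mol = Chem.Mol(mol)
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    mol = _canonical_renumber(mol)
    return IndexedMolecule(rdmol=mol, source_smiles=source or Chem.MolToSmiles(mol))


def canonical_smiles(mol: "IndexedMolecule | Chem.Mol | str") -> str:
    """Deterministic canonical isomeric SMILES (stereo preserved)."""
    if isinstance(mol, str):
        mol = parse_molecule(mol)
    rd = mol.rdmol if isinstance(mol, IndexedMolecule) else mol
    try:
        out = Chem.MolToSmiles(rd)
    except Exception as exc:  # pragma: no cover - defensive
        raise MoleculeError(f"cannot serialize molecule: {exc}") from exc
    if out is None or out == "":
        raise MoleculeError("cannot serialize molecule")
    return out


def morgan_bits(mol: IndexedMolecule) -> frozenset[int]:
    """Set of on-bits of the fixed Morgan fingerprint (radius 2, 2048 bits)."""
    fp = rdMolDescriptors.GetMorganFingerprintAsBitVect(
        mol.rdmol, FINGERPRINT_RADIUS, nBits=FINGERPRINT_BITS
    )
    return frozenset(fp.GetOnBits())


def tanimoto_similarity(a: IndexedMolecule, b: IndexedMolecule) -> float:
    """Jaccard index of Morgan fingerprint bit sets, in [0, 1].

    Both fingerprints empty (possible for single-atom molecules) is defined
    as 1.0 when the canonical SMILES agree and 0.0 otherwise.
    """
    ba, bb = morgan_bits(a), morgan_bits(b)
    union = ba | bb
    if not union:
        return 1.0 if canonical_smiles(a) == canonical_smiles(b) else 0.0
    return len(ba & bb) / len(union)


@dataclass
class Reaction:
    """An atom-mapped reaction ``reactants >> product``.

    ``atom_map`` sends a product atom_id to ``(reactant_index, reactant
    atom_id)``; it is partial (unmapped product atoms leave, unmapped
    reactant atoms arrive) and injective.
    """

    reactants: list[IndexedMolecule]
    product: IndexedMolecule
    atom_map: dict[int, tuple[int, int]] = field(default_factory=dict)
    ec: Optional["object"] = None  # ECNumber; kept loose to avoid a cycle

    def __post_init__(self):
        seen: set[tuple[int, int]] = set()
        for pid, (ri, rai) in self.atom_map.items():
            if (ri, rai) in seen:
                raise MoleculeError(
                    f"atom map not injective: reactant atom {ri}:{rai} used twice"
                )
            seen.add((ri, rai))
            psym = self.product.rdmol.GetAtomWithIdx(pid).GetSymbol()
            rsym = self.reactants[ri].rdmol.GetAtomWithIdx(rai).GetSymbol()
            if psym != rsym:
                raise MoleculeError(
                    f"mapped atoms differ in element: product {pid} ({psym}) vs "
                    f"reactant {ri}:{rai} ({rsym})"
                )

    def smiles(self) -> str:
        left = ".".join(m.smiles() for m in self.reactants)
        return f"{left}>>{self.product.smiles()}"

    def mapped_smiles(self) -> str:
        """Reaction SMILES with ``:n`` atom maps (n = product atom_id + 1)."""
        prod = Chem.Mol(self.product.rdmol)
        for a in prod.GetAtoms():
            a.SetAtomMapNum(a.GetIdx() + 1)
        rs = [Chem.Mol(m.rdmol) for m in self.reactants]
        for pid, (ri, rai) in self.atom_map.items():
            rs[ri].GetAtomWithIdx(rai).SetAtomMapNum(pid + 1)
        left = ".".join(Chem.MolToSmiles(m) for m in rs)
        return f"{left}>>{Chem.MolToSmiles(prod)}"


def _parse_mapped_side(smiles: str) -> tuple[IndexedMolecule, dict[int, int]]:
    """Parse one reaction side; return molecule + {atom_id: map_number}."""
    _check_delimiters(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"SMILES parse error: cannot parse {smiles!r}")
    mapnums = {a.GetIdx(): a.GetAtomMapNum() for a in mol.GetAtoms()}
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    inverse = [0] * len(ranks)
    for idx, rank in enumerate(ranks):
        inverse[rank] = idx
    mol = Chem.RenumberAtoms(mol, inverse)
    # after renumbering, new index i held old index inverse[i]
    id_to_map = {i: mapnums[inverse[i]] for i in range(len(inverse))}
    return IndexedMolecule(rdmol=mol, source_smiles=smiles), id_to_map


def parse_reaction(rxn_smiles: str, ec=None) -> Reaction:
    """Parse ``reactants>>product`` with optional ``:n`` atom maps.

    Also accepts the ECREACT-style dialect ``reactants|a.b.c.d>>product``;
    the embedded EC annotation takes effect unless ``ec`` is given.
    """
    if ">>" not in rxn_smiles:
        raise MoleculeError(f"not a reaction SMILES (missing '>>'): {rxn_smiles!r}")
    left, right = rxn_smiles.split(">>", 1)
    if "|" in left:
        left, ec_text = left.rsplit("|", 1)
        if ec is None:
            from .enzyme_eval import ECNumber

            ec = ECNumber.parse(ec_text)
    product, prod_map = _parse_mapped_side(right)
    reactants: list[IndexedMolecule] = []
    react_maps: list[dict[int, int]] = []
    for part in left.split("."):
        m, mm = _parse_mapped_side(part)
        reactants.append(m)
        react_maps.append(mm)
    # invert: map number -> (reactant index, atom id)
    by_num: dict[int, tuple[int, int]] = {}
    for ri, mm in enumerate(react_maps):
        for aid, num in mm.items():
            if num > 0:
                if num in by_num:
                    raise MoleculeError(f"atom map number {num} used twice on reactant side")
                by_num[num] = (ri, aid)
    atom_map = {
        pid: by_num[num]
        for pid, num in prod_map.items()
        if num > 0 and num in by_num
    }
    return Reaction(reactants=reactants, product=product, atom_map=atom_map, ec=ec)
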