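"""Edit codec: grammar fidelity, application semantics, extraction
round-trip."""

import pytest
from hypothesis import given, strategies as st

from enzedit.chemgraph import canonical_smiles, parse_molecule, parse_reaction
from enzedit.enzyme_eval import ECNumber
from enzedit.ssredits import (
    ApplicationError,
    SSREdit,
    SSREditScript,
    ScriptError,
    ScriptParseError,
    ValidityError,
    apply_edits,
    extract_edits,
    parse_script,
    script_text,
    serialize_script,
)

PAPER_GROUP = "*[S@@+](CC[C@H](N)C(=O)O)C[C@H]1O[C@@H](n2cnc3c(N)ncnc32)[C@H](O)[C@@H]1O"


class TestGrammar:
    def test_delete_bond_printed_form(self):
        s = SSREditScript(
            (
                SSREdit("DeleteBond", bond_sites=(7, 8), bond_symbol="CN"),
                SSREdit("Terminate"),
            )
        )
        assert script_text(s) == "[Delete][Bond]CN: 7.8 [Terminate]"

    def test_attach_group_printed_form(self):
        s = SSREditScript(
            (
                SSREdit("AttachGroup", group_smiles=PAPER_GROUP, site=8),
                SSREdit("Terminate"),
            )
        )
        assert script_text(s) == f"[Attach][Group]{PAPER_GROUP}: 8 [Terminate]"

    def test_change_atom_printed_form(self):
        s = SSREditScript(
            (SSREdit("ChangeAtom", atom_symbol="N", site=7), SSREdit("Terminate"))
        )
        assert script_text(s) == "[Change][Atom]N: 7 [Terminate]"

    def test_parse_full_worked_sequence(self):
        s = parse_script(
            "[Delete][Bond]CN: 7.8 [Attach][Group]*O: 8 "
            "[Change][Atom]N: 7 [Terminate] [EC] 2 1 1 71"
        )
        assert len(s.structural) == 3
        assert str(s.annotated_ec) == "2.1.1.71"

    @pytest.mark.parametrize(
        "bad",
        [
            "[Delete][Atom]",
            "[Delete][Bond]CN: 7",
            "[Change][Bond]CO: 1.2",  # missing order token
            "[Delete][Bond]CN: 7.8",  # missing Terminate
            "[EC] 2 1 1",  # short EC
            "[Terminate] [Delete][Bond]CN: 1.2 [Terminate]",
        ],
    )
    def test_malformed_sequences_raise(self, bad):
        with pytest.raises(ScriptParseError):
            parse_script(bad)

    def test_script_invariants_enforced(self):
        with pytest.raises(ScriptError):
            SSREditScript((SSREdit("Terminate"), SSREdit("Terminate")))
        with pytest.raises(ScriptError):
            SSREdit("DeleteBond", bond_sites=(3, 3), bond_symbol="CC")
        with pytest.raises(ScriptError):
            SSREdit("AttachGroup", group_smiles="CC", site=1)  # no wildcard

    def test_bijectivity_on_fixture_scripts(self, fixture_set):
        for _, script in fixture_set.reactions:
            toks = serialize_script(script)
            back = parse_script(toks)
            assert script_text(back) == " ".join(toks)
            assert back == script

    @given(
        st.lists(
            st.sampled_from(
                [
                    SSREdit("DeleteBond", bond_sites=(0, 3), bond_symbol="CO"),
                    SSREdit("ChangeBond", bond_sites=(1, 2), bond_symbol="CC",
                            new_bond_order="="),
                    SSREdit("AddBond", bond_sites=(2, 5), bond_symbol="CN",
                            new_bond_order="-"),
                    SSREdit("AttachGroup", group_smiles="*C(=O)O", site=4),
                    SSREdit("LeaveGroup", group_smiles="*OC"),
                    SSREdit("ChangeAtom", atom_symbol="N+", site=6),
                    SSREdit("ChangeAtom", atom_symbol="C@S", site=2),
                ]
            ),
            max_size=5,
        ),
        st.booleans(),
    )
    def test_serialize_parse_identity(self, structural, with_ec):
        edits = tuple(structural) + (SSREdit("Terminate"),)
        if with_ec:
            edits += (SSREdit("EC", ec=ECNumber.parse("1.14.13.-")),)
        script = SSREditScript(edits)
        assert parse_script(serialize_script(script)) == script


class TestApply:
    def test_terminate_alone_is_identity(self):
        mol = parse_molecule("CC(=O)OCC")
        out = apply_edits(mol, SSREditScript((SSREdit("Terminate"),)))
        assert [m.smiles() for m in out] == [mol.smiles()]

    def test_ester_script_materializes_acid_and_alcohol(self):
        mol = parse_molecule("CC(=O)OCC")
        # ester C-O bond in canonical indexing: acyl C=5, ester O=4
        script = parse_script("[Delete][Bond]OC: 4.5 [Attach][Group]*O: 5 [Terminate]")
        out = sorted(m.smiles() for m in apply_edits(mol, script))
        assert out == sorted([canonical_smiles("CC(=O)O"), canonical_smiles("CCO")])

    def test_change_atom_neutralizes_and_repairs_hydrogens(self):
        mol = parse_molecule("CC[NH3+]")
        nid = next(a.atom_id for a in mol.atoms if a.symbol == "N")
        script = parse_script(f"[Change][Atom]N: {nid} [Terminate]")
        (out,) = apply_edits(mol, script)
        assert out.smiles() == canonical_smiles("CCN")
        a = next(a for a in out.atoms if a.symbol == "N")
        assert a.formal_charge == 0 and a.implicit_h == 2

    def test_missing_bond_raises_application_error(self):
        mol = parse_molecule("CCO")
        bonded = {frozenset(b[:2]) for b in mol.bonds}
        i, j = next(
            (i, j)
            for i in range(3)
            for j in range(i + 1, 3)
            if frozenset((i, j)) not in bonded
        )
        with pytest.raises(ApplicationError):
            apply_edits(
                mol,
                SSREditScript(
                    (
                        SSREdit("DeleteBond", bond_sites=(i, j), bond_symbol="CC"),
                        SSREdit("Terminate"),
                    )
                ),
            )

    def test_missing_atom_raises_application_error(self):
        mol = parse_molecule("CCO")
        with pytest.raises(ApplicationError):
            apply_edits(
                mol,
                SSREditScript(
                    (
                        SSREdit("ChangeAtom", atom_symbol="N", site=99),
                        SSREdit("Terminate"),
                    )
                ),
            )

    def test_unsatisfiable_valence_raises_validity_error(self):
        mol = parse_molecule("CC")
        script = SSREditScript(
            (
                SSREdit("ChangeBond", bond_sites=(0, 1), bond_symbol="CC",
                        new_bond_order="#"),
                SSREdit("AttachGroup", group_smiles="*O", site=0),
                SSREdit("AttachGroup", group_smiles="*O", site=0),
                SSREdit("Terminate"),
            )
        )
        with pytest.raises((ValidityError, ApplicationError)):
            apply_edits(mol, script)

    def test_never_returns_invalid_molecules(self, fixture_set):
        from rdkit import Chem

        for rxn, script in fixture_set.reactions[:50]:
            for m in apply_edits(rxn.product, script):
                assert Chem.MolFromSmiles(m.smiles()) is not None


class TestExtract:
    def test_identity_reaction_gives_bare_terminate(self):
        rxn = parse_reaction("[CH3:1][CH2:2][OH:3]>>[CH3:1][CH2:2][OH:3]")
        assert script_text(extract_edits(rxn)) == "[Terminate]"

    def test_ester_hydrolysis_extraction(self):
        rxn = parse_reaction(
            "[CH3:1][C:2](=[O:3])[OH:7].[OH:4][CH2:5][CH3:6]"
            ">>[CH3:1][C:2](=[O:3])[O:4][CH2:5][CH3:6]"
        )
        script = extract_edits(rxn)
        actions = [e.action for e in script.edits]
        assert actions == ["DeleteBond", "AttachGroup", "Terminate"]
        got = sorted(m.smiles() for m in apply_edits(rxn.product, script))
        assert got == sorted(m.smiles() for m in rxn.reactants)

    def test_retro_reduction_is_single_bond_change(self):
        rxn = parse_reaction("[CH3:1][CH:2]=[O:3]>>[CH3:1][CH2:2][OH:3]")
        script = extract_edits(rxn)
        assert [e.action for e in script.edits] == ["ChangeBond", "Terminate"]
        assert [m.smiles() for m in apply_edits(rxn.product, script)] == [
            canonical_smiles("CC=O")
        ]

    def test_free_cofactor_reactant_round_trips(self):
        """A wholly unmapped reactant (cofactor) must come back as a
        separate component."""
        rxn = parse_reaction("[CH3:1][CH2:2][OH:3].O=P(O)(O)O>>[CH3:1][CH2:2][OH:3]")
        script = extract_edits(rxn)
        assert any(
            e.action == "AttachGroup" and e.group_smiles.startswith("*.")
            for e in script.edits
        )
        got = sorted(m.smiles() for m in apply_edits(rxn.product, script))
        assert got == sorted(m.smiles() for m in rxn.reactants)

    def test_round_trip_on_full_fixture_set(self, fixture_set):
        """The module's primary oracle: extraction then application
        reproduces every fixture's reactant set under canonical SMILES."""
        failures = []
        for rxn, _ in fixture_set.reactions:
            script = extract_edits(rxn)
            got = sorted(m.smiles() for m in apply_edits(rxn.product, script))
            want = sorted(m.smiles() for m in rxn.reactants)
            if got != want:
                failures.append((rxn.smiles(), got, want))
        assert not failures, failures[:3]

    def test_relabelled_reaction_gives_substituted_script(self):
        """Respelling the product SMILES (same molecule, different atom
        order) must give the identical script, because IDs are canonical."""
        from rdkit import Chem

        base = "[CH3:1][C:2](=[O:3])[O:4][CH2:5][CH3:6]"
        rxn = parse_reaction(
            f"[CH3:1][C:2](=[O:3])[OH:7].[OH:4][CH2:5][CH3:6]>>{base}"
        )
        ref = script_text(extract_edits(rxn))
        mol = Chem.MolFromSmiles(base)
        respelled = Chem.MolToSmiles(mol, doRandom=True, canonical=False)
        rxn2 = parse_reaction(
            f"[CH3:1][C:2](=[O:3])[OH:7].[OH:4][CH2:5][CH3:6]>>{respelled}"
        )
        assert script_text(extract_edits(rxn2)) == ref

    def test_ec_annotation_appended_last(self, fixture_set):
        for rxn, _ in fixture_set.reactions[:20]:
            script = extract_edits(rxn)
            assert script.edits[-1].action == "EC"
            assert script.edits[-2].action == "Terminate"
            assert script.annotated_ec == rxn.ec
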