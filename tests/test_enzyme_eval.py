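"""EC-number model and evaluation metrics, cross-checked against
independent implementations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef

from enzedit.chemgraph import parse_reaction
from enzedit.enzyme_eval import (
    ECNumber,
    EvalRecord,
    build_eval_input,
    classification_scores,
    evaluation_report,
    read_ecreact_line,
    topk_exact_match,
    truncate_ec,
    write_ecreact_line,
)


class TestECNumber:
    @pytest.mark.parametrize(
        "text,level",
        [("1.1.1.103", 4), ("4.1.1.24", 4), ("2.6.1.-", 3), ("3.-.-.-", 1)],
    )
    def test_parse_and_level(self, text, level):
        ec = ECNumber.parse(text)
        assert ec.level == level
        assert str(ec) == text

    def test_wildcards_must_be_suffix(self):
        with pytest.raises(ValueError):
            ECNumber((1, None, 1, 1))

    @pytest.mark.parametrize(
        "text,level,expected",
        [("1.1.1.103", 3, "1.1.1.-"), ("4.1.1.24", 1, "4.-.-.-")],
    )
    def test_truncation(self, text, level, expected):
        assert str(truncate_ec(ECNumber.parse(text), level)) == expected

    def test_truncation_beyond_specificity_errors(self):
        with pytest.raises(ValueError):
            truncate_ec(ECNumber.parse("2.6.1.-"), 4)

    @given(st.lists(st.integers(1, 80), min_size=4, max_size=4), st.integers(1, 4))
    def test_truncate_level_matches_request(self, fields, level):
        ec = ECNumber(tuple(fields))
        assert truncate_ec(ec, level).level == level


class TestBuildEvalInput:
    def _rxn(self):
        return parse_reaction("[CH3:1][CH2:2][OH:3]>>[CH3:1][CH2:2][OH:3]")

    def test_product_mode_is_product_tokens_only(self):
        toks = list(build_eval_input(self._rxn(), "Product"))
        assert "[SEP]" not in toks and ">>" not in toks

    def test_edits_mode_on_identity_ends_with_terminate(self):
        toks = list(build_eval_input(self._rxn(), "Product+SSREdits"))
        sep = toks.index("[SEP]")
        assert toks[sep + 1 :] == ["[Terminate]"]

    def test_reactants_mode_joins_with_dot_and_sep(self):
        rxn = parse_reaction(
            "[CH3:1][C:2](=[O:3])[OH:7].[OH:4][CH2:5][CH3:6]"
            ">>[CH3:1][C:2](=[O:3])[O:4][CH2:5][CH3:6]"
        )
        toks = list(build_eval_input(rxn, "Product+Reactants"))
        assert toks.count("[SEP]") == 1
        assert "." in toks[toks.index("[SEP]") :]

    def test_overlength_raises_instead_of_truncating(self):
        rxn = parse_reaction("C" * 200 + ">>" + "C" * 200)
        with pytest.raises(ValueError):
            build_eval_input(rxn, "Product+Reactants")


def _rec(truth_rank, k_total=12):
    """A record whose truth sits at the given 1-based rank."""
    truth = ECNumber.parse("1.1.1.1")
    preds = [ECNumber((2, i + 1, 1, 1)) for i in range(k_total)]
    if truth_rank <= k_total:
        preds[truth_rank - 1] = truth
    return EvalRecord(input_mode="Product", predictions=preds, truth=truth)


class TestTopK:
    def test_rank_two_misses_top1_hits_top3(self):
        r = _rec(2)
        assert topk_exact_match([r], 1) == 0.0
        assert topk_exact_match([r], 3) == 1.0

    def test_perfect_predictions_all_k(self):
        recs = [_rec(1) for _ in range(5)]
        for k in (1, 3, 5, 10):
            assert topk_exact_match(recs, k) == 1.0

    def test_matches_brute_force_rank_scan(self):
        ranks = [1, 1, 2, 3, 5, 11, 4, 9, 1, 7]
        recs = [_rec(r) for r in ranks]
        for k in (1, 2, 3, 5, 10):
            expected = sum(r <= k for r in ranks) / len(ranks)
            assert topk_exact_match(recs, k) == pytest.approx(expected)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(0)
        recs = [_rec(int(rng.integers(1, 15))) for _ in range(30)]
        vals = [topk_exact_match(recs, k) for k in (1, 3, 5, 10)]
        assert vals == sorted(vals)

    def test_joint_script_and_ec_must_both_match(self):
        truth = ("[Terminate]", ECNumber.parse("1.1.1.1"))
        r = EvalRecord(
            input_mode="Product+SSREdits",
            predictions=[
                ("[Terminate]", ECNumber.parse("2.1.1.1")),
                ("[Delete][Bond]CC: 0.1 [Terminate]", ECNumber.parse("1.1.1.1")),
                ("[Terminate]", ECNumber.parse("1.1.1.1")),
            ],
            truth=truth,
        )
        assert topk_exact_match([r], 2) == 0.0
        assert topk_exact_match([r], 3) == 1.0

    def test_level_accuracy_monotone_on_truncation_consistent_labels(self):
        """Coarser EC levels can only match more often."""
        rng = np.random.default_rng(3)
        recs = []
        for _ in range(40):
            truth = ECNumber(tuple(int(x) for x in rng.integers(1, 4, 4)))
            preds = [ECNumber(tuple(int(x) for x in rng.integers(1, 4, 4))) for _ in range(5)]
            recs.append(EvalRecord("Product", preds, truth))
        accs = [topk_exact_match(recs, 3, level=L) for L in (1, 2, 3, 4)]
        assert all(accs[i] >= accs[i + 1] for i in range(3))

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            topk_exact_match([_rec(1)], 0)


class TestClassificationScores:
    def test_perfect_predictions(self):
        acc, mcc, f1 = classification_scores(["a", "b", "c"], ["a", "b", "c"])
        assert (acc, mcc, f1) == (1.0, 1.0, 1.0)

    def test_single_class_truth_mcc_zero(self):
        acc, mcc, f1 = classification_scores(["a", "a"], ["a", "a"])
        assert acc == 1.0 and mcc == 0.0

    def test_three_class_matrix_matches_defining_formulas(self):
        pred = ["a", "b", "b", "c", "a", "c", "b", "a", "c", "b"]
        true = ["a", "b", "c", "c", "b", "c", "b", "a", "a", "b"]
        acc, mcc, f1 = classification_scores(pred, true)
        assert acc == pytest.approx(accuracy_score(true, pred))
        assert mcc == pytest.approx(matthews_corrcoef(true, pred))
        assert f1 == pytest.approx(f1_score(true, pred, average="macro"))

    def test_agrees_with_reference_on_random_label_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            n_classes = int(rng.integers(2, 6))
            true = [f"c{int(x)}" for x in rng.integers(0, n_classes, n)]
            pred = [f"c{int(x)}" for x in rng.integers(0, n_classes, n)]
            acc, mcc, f1 = classification_scores(pred, true)
            assert acc == pytest.approx(accuracy_score(true, pred))
            assert mcc == pytest.approx(matthews_corrcoef(true, pred), abs=1e-12)
            labels = sorted(set(true) | set(pred))
            assert f1 == pytest.approx(
                f1_score(true, pred, average="macro", labels=labels, zero_division=0)
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_scores(["a"], ["a", "b"])


class TestECReactDialect:
    def test_read_write_round_trip(self):
        line = "NCCCCN.O|3.5.3.11>>N=C(N)NCCCCN"
        rxn = read_ecreact_line(line)
        assert str(rxn.ec) == "3.5.3.11"
        again = read_ecreact_line(write_ecreact_line(rxn))
        assert str(again.ec) == "3.5.3.11"
        assert again.product.smiles() == rxn.product.smiles()

    def test_wildcard_suffix_tolerated(self):
        rxn = read_ecreact_line("CCO|2.6.1.->>CC=O")
        assert str(rxn.ec) == "2.6.1.-"


def test_evaluation_report_shape():
    recs = [_rec(r) for r in (1, 2, 6)]
    rep = evaluation_report(recs, ks=(1, 3), levels=(1, 4))
    assert rep["n_records"] == 3
    assert set(rep["topk"]) == {"level_1", "level_4"}
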