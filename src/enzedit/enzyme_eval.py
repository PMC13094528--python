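"""EC-number data model and evaluation protocol.

Enzyme Commission numbers are four-field hierarchical labels
(``class.subclass.sub-subclass.serial``); coarser levels are written with
wildcard suffixes, e.g. ``2.6.1.-``.  Evaluation supports three input
configurations (product only, product+reactants, product+edit script),
Top-k exact match over ranked beam candidates, and multiclass
accuracy / Matthews correlation / macro-F1 at each of the four EC levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

__all__ = [
    "ECNumber",
    "EvalRecord",
    "truncate_ec",
    "build_eval_input",
    "topk_exact_match",
    "classification_scores",
    "read_ecreact_line",
    "write_ecreact_line",
    "evaluation_report",
    "INPUT_MODES",
]

INPUT_MODES = ("Product", "Product+Reactants", "Product+SSREdits")

#: token budget shared with the sequence model
CONTEXT_LIMIT = 256


@dataclass(frozen=True)
class ECNumber:
    """Four-field EC label; ``None`` fields are wildcards ('-')."""

    fields: tuple[Optional[int], Optional[int], Optional[int], Optional[int]]

    def __post_init__(self):
        if len(self.fields) != 4:
            raise ValueError("ECNumber needs exactly four fields")
        seen_wild = False
        for f in self.fields:
            if f is None:
                seen_wild = True
            else:
                if seen_wild:
                    raise ValueError(
                        f"wildcards must form a suffix: {self.fields}"
                    )
                if f <= 0:
                    raise ValueError(f"EC fields are positive integers: {self.fields}")

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        parts = text.strip().split(".")
        if len(parts) != 4:
            raise ValueError(f"not an EC number: {text!r}")
        fields = tuple(None if p in ("-", "") else int(p) for p in parts)
        return cls(fields)

    @property
    def level(self) -> int:
        """Count of specified leading fields (1-4)."""
        n = 0
        for f in self.fields:
            if f is None:
                break
            n += 1
        return n

    def __str__(self) -> str:
        return ".".join("-" if f is None else str(f) for f in self.fields)


def truncate_ec(ec: ECNumber, level: int) -> ECNumber:
    """Keep the first ``level`` fields, wildcard the rest."""
    if not 1 <= level <= 4:
        raise ValueError(f"EC level must be in 1..4, got {level}")
    if ec.level < level:
        raise ValueError(
            f"EC {ec} is only specified to level {ec.level}, cannot "
            f"compare at level {level}"
        )
    return ECNumber(tuple(ec.fields[:level]) + (None,) * (4 - level))


def build_eval_input(reaction, mode: str, script=None):
    """Tokenized model input for one of the three input configurations.

    Molecules are joined with ``.``; segments (product / reactants or
    product / script) are joined with a ``[SEP]`` token.  Over-length
    inputs raise rather than silently truncate.
    """
    from .chemgraph import TokenSequence, tokenize_smiles

    if mode not in INPUT_MODES:
        raise ValueError(f"unknown input mode {mode!r}")
    tokens = list(tokenize_smiles(reaction.product.smiles()))
    if mode == "Product+Reactants":
        tokens.append("[SEP]")
        tokens.extend(tokenize_smiles(".".join(m.smiles() for m in reaction.reactants)))
    elif mode == "Product+SSREdits":
        if script is None:
            from .ssredits import extract_edits

            script = extract_edits(reaction)
        from .ssredits import serialize_script

        tokens.append("[SEP]")
        tokens.extend(serialize_script(script))
    if len(tokens) > CONTEXT_LIMIT:
        raise ValueError(
            f"input of {len(tokens)} tokens exceeds the {CONTEXT_LIMIT}-token context"
        )
    return TokenSequence(tuple(tokens))


@dataclass
class EvalRecord:
    """Ranked predictions against one ground truth.

    Predictions are either ``ECNumber`` or ``(script_text, ECNumber)``
    pairs (joint edit+enzyme match); truth has the same shape.
    """

    input_mode: str
    predictions: list
    truth: object

    def __post_init__(self):
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if not self.predictions:
            raise ValueError("record needs at least one prediction")


def _match(pred, truth, level: Optional[int]) -> bool:
    if isinstance(truth, tuple):
        ps, pec = pred
        ts, tec = truth
        if ps != ts:
            return False
        pred, truth = pec, tec
    if level is None:
        return pred == truth
    if pred.level < level or truth.level < level:
        return False
    return truncate_ec(pred, level) == truncate_ec(truth, level)


def topk_exact_match(records: Sequence[EvalRecord], k: int, level: Optional[int] = None) -> float:
    """Fraction of records whose truth appears within ranks 1..k.

    Joint records require both the canonical script text and the EC number
    to match.  ``level`` optionally truncates both EC sides before
    comparison.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not records:
        raise ValueError("no records")
    hits = 0
    for r in records:
        if any(_match(p, r.truth, level) for p in r.predictions[:k]):
            hits += 1
    return hits / len(records)


def classification_scores(
    pred_labels: Sequence, true_labels: Sequence
) -> tuple[float, float, float]:
    """Multiclass (accuracy, MCC, macro-F1) from the confusion matrix.

    MCC on a zero-variance side (single observed class) is defined as 0 by
    the usual convention.  F1 is macro-averaged over the classes present
    in either side, with per-class F1 of 0 when undefined.
    """
    if len(pred_labels) != len(true_labels):
        raise ValueError("label lists differ in length")
    if not true_labels:
        raise ValueError("empty label lists")
    pred = [str(x) for x in pred_labels]
    true = [str(x) for x in true_labels]
    classes = sorted(set(pred) | set(true))
    idx = {c: i for i, c in enumerate(classes)}
    n = len(classes)
    cm = [[0] * n for _ in range(n)]
    for p, t in zip(pred, true):
        cm[idx[t]][idx[p]] += 1
    total = len(true)
    correct = sum(cm[i][i] for i in range(n))
    accuracy = correct / total

    # multiclass MCC from the full confusion matrix (R_k statistic)
    t_k = [sum(cm[i]) for i in range(n)]  # truths per class
    p_k = [sum(cm[i][j] for i in range(n)) for j in range(n)]  # predictions per class
    cov_tp = correct * total - sum(tk * pk for tk, pk in zip(t_k, p_k))
    var_t = total * total - sum(tk * tk for tk in t_k)
    var_p = total * total - sum(pk * pk for pk in p_k)
    mcc = 0.0 if var_t == 0 or var_p == 0 else cov_tp / (var_t * var_p) ** 0.5

    f1s = []
    for j in range(n):
        tp = cm[j][j]
        denom = t_k[j] + p_k[j]
        f1s.append(0.0 if denom == 0 else 2 * tp / denom)
    return accuracy, mcc, sum(f1s) / n


def read_ecreact_line(line: str):
    """Parse one ECREACT-dialect reaction: ``reactants|a.b.c.d>>product``.

    The EC annotation is embedded on the substrate side; wildcard suffixes
    are tolerated.  Returns a mapped/unmapped :class:`Reaction` whose
    ``ec`` attribute carries the label.
    """
    from .chemgraph import parse_reaction

    return parse_reaction(line.strip())


def write_ecreact_line(reaction) -> str:
    """Serialize a reaction back to the ECREACT dialect."""
    left = ".".join(m.smiles() for m in reaction.reactants)
    ec = f"|{reaction.ec}" if reaction.ec is not None else ""
    return f"{left}{ec}>>{reaction.product.smiles()}"


def evaluation_report(
    records: Sequence[EvalRecord],
    ks: Iterable[int] = (1, 3, 5, 10),
    levels: Iterable[int] = (1, 2, 3, 4),
) -> dict:
    """Top-k exact-match table over EC levels, as a JSON-ready dict."""
    out = {"n_records": len(records), "topk": {}}
    for level in levels:
        out["topk"][f"level_{level}"] = {
            f"top{k}": topk_exact_match(records, k, level=level) for k in ks
        }
    return out


def report_text(report: dict) -> str:
    """Plain-text table rendering of :func:`evaluation_report`."""
    lines = [f"records: {report['n_records']}"]
    for level, row in report["topk"].items():
        cells = "  ".join(f"{k}={v:.4f}" for k, v in row.items())
        lines.append(f"{level}: {cells}")
    return "\n".join(lines)
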