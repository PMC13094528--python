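"""Encoder-decoder sequence model: configuration, training, beam search.

The architecture follows the relative-position-bias encoder-decoder
family: pre-RMSNorm blocks of multi-head self-attention (bucketed
relative position bias added to the logits), cross-attention in the
decoder, and a ReLU feed-forward inner layer; embeddings are tied with
the output projection.  The published-scale configuration (6+6 blocks,
model dim 256, 12 heads of 64, FFN 2048, 32 relative buckets, max
relative distance 128, 256-token context) ships as the default
:class:`ModelConfig`; a tiny desk-scale profile is used for tests and
sanity training runs.

Optimization is AdamW (beta1 0.9, beta2 0.999) under a linear warmup to
the peak learning rate followed by a 2% multiplicative decay after every
10,000 training steps.

Everything runs on NumPy via the package's own reverse-mode autodiff
(:mod:`enzedit.autograd`); at desk scale the model is exercised on tiny
synthetic corpora only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .autograd import Tensor, constant, parameter
from .chemgraph import TokenSequence
from .pretrain import TrainingExample

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "Vocabulary",
    "Prediction",
    "Checkpoint",
    "build_vocab",
    "learning_rate",
    "train",
    "beam_decode",
    "greedy_decode",
    "teacher_forced_accuracy",
]

logger = logging.getLogger(__name__)

PAD, UNK, START, END = "[PAD]", "[UNK]", "[START]", "[END]"
SPECIALS = (PAD, UNK, START, END, "[MASK]", "[SEP]")


@dataclass(frozen=True)
class ModelConfig:
    encoder_blocks: int = 6
    decoder_blocks: int = 6
    model_dim: int = 256
    heads: int = 12
    head_dim: int = 64
    ffn_dim: int = 2048
    rel_buckets: int = 32
    rel_max_distance: int = 128
    context_len: int = 256
    dropout: float = 0.10

    def __post_init__(self):
        ints = (
            self.encoder_blocks,
            self.decoder_blocks,
            self.model_dim,
            self.heads,
            self.head_dim,
            self.ffn_dim,
            self.rel_buckets,
            self.rel_max_distance,
            self.context_len,
        )
        if any(v < 1 for v in ints):
            raise ValueError("all ModelConfig sizes must be positive integers")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def tiny(cls) -> "ModelConfig":
        """Desk-scale profile for CPU sanity training."""
        return cls(
            encoder_blocks=2,
            decoder_blocks=2,
            model_dim=64,
            heads=4,
            head_dim=16,
            ffn_dim=128,
            rel_buckets=16,
            rel_max_distance=32,
            context_len=256,
            dropout=0.0,
        )


@dataclass(frozen=True)
class TrainConfig:
    beta1: float = 0.9
    beta2: float = 0.999
    peak_lr: float = 5e-5
    warmup_steps: int = 100
    lr_decay_rate: float = 0.02  # per 10,000 steps
    decay_interval: int = 10_000
    weight_decay: float = 0.0
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.peak_lr <= 0:
            raise ValueError("peak_lr must be positive")


def learning_rate(cfg: TrainConfig, step: int) -> float:
    """Closed-form schedule value at 1-based ``step``.

    Linear warmup to ``peak_lr`` over ``warmup_steps``, then the rate
    multiplies by ``1 - lr_decay_rate`` after every ``decay_interval``
    completed steps.
    """
    if step < 1:
        raise ValueError("step is 1-based")
    warm = min(1.0, step / max(1, cfg.warmup_steps))
    decay = (1.0 - cfg.lr_decay_rate) ** ((step - 1) // cfg.decay_interval)
    return cfg.peak_lr * warm * decay


@dataclass(frozen=True)
class Vocabulary:
    token_to_id: dict[str, int]

    def __post_init__(self):
        ids = list(self.token_to_id.values())
        if len(set(ids)) != len(ids):
            raise ValueError("vocabulary ids must be unique")
        if self.token_to_id.get(PAD) != 0:
            raise ValueError("id 0 is reserved for [PAD]")

    def __len__(self):
        return len(self.token_to_id)

    @property
    def id_to_token(self) -> dict[int, str]:
        return {v: k for k, v in self.token_to_id.items()}

    def encode(self, tokens: Iterable[str]) -> list[int]:
        unk = self.token_to_id[UNK]
        out = []
        for t in tokens:
            if t not in self.token_to_id:
                logger.warning("unseen token %r mapped to %s", t, UNK)
            out.append(self.token_to_id.get(t, unk))
        return out

    def decode(self, ids: Iterable[int]) -> list[str]:
        rev = self.id_to_token
        return [rev[i] for i in ids]

    def to_json(self) -> str:
        return json.dumps(self.token_to_id, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        return cls(json.loads(text))


def build_vocab(corpus: Sequence[TrainingExample]) -> Vocabulary:
    """Specials first (fixed order), then observed tokens lexicographically."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    seen: set[str] = set()
    for ex in corpus:
        seen.update(ex.input)
        seen.update(ex.target)
    mapping = {tok: i for i, tok in enumerate(SPECIALS)}
    for tok in sorted(seen - set(SPECIALS)):
        mapping[tok] = len(mapping)
    return Vocabulary(mapping)


@dataclass(frozen=True)
class Prediction:
    """One ranked beam candidate."""

    tokens: TokenSequence
    token_confidences: tuple[float, ...]
    sequence_score: float
    rank: int

    def __post_init__(self):
        if len(self.tokens) != len(self.token_confidences):
            raise ValueError("one confidence per token required")
        if any(not 0 < c <= 1 for c in self.token_confidences):
            raise ValueError("token confidences must lie in (0, 1]")

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


# ---------------------------------------------------------------------------
# parameters and forward pass


def _relative_buckets(qlen: int, klen: int, buckets: int, max_dist: int, causal: bool) -> np.ndarray:
    """Bucketed relative positions (key pos - query pos), T5 scheme:
    half the buckets cover exact small offsets, the rest are log-spaced."""
    ctx = np.arange(qlen)[:, None]
    mem = np.arange(klen)[None, :]
    rel = mem - ctx
    if causal:
        n = -np.minimum(rel, 0)
        num = buckets
        out = np.zeros_like(n)
    else:
        num = buckets // 2
        out = (rel > 0).astype(np.int64) * num
        n = np.abs(rel)
    max_exact = num // 2
    is_small = n < max_exact
    log_big = max_exact + (
        np.log(np.maximum(n, 1) / max_exact)
        / np.log(max(max_dist / max_exact, 1.0 + 1e-9))
        * (num - max_exact)
    ).astype(np.int64)
    log_big = np.minimum(log_big, num - 1)
    return out + np.where(is_small, n, log_big)


def _init_params(cfg: ModelConfig, vocab_size: int, rng: np.random.Generator) -> dict[str, Tensor]:
    d, h, dh, f = cfg.model_dim, cfg.heads, cfg.head_dim, cfg.ffn_dim
    inner = h * dh
    p: dict[str, Tensor] = {}

    def w(name, shape, scale):
        p[name] = parameter(rng.normal(0.0, scale, size=shape))

    w("embed", (vocab_size, d), d**-0.5)
    for side, blocks in (("enc", cfg.encoder_blocks), ("dec", cfg.decoder_blocks)):
        w(f"{side}_relbias", (cfg.rel_buckets, h), 0.02)
        for b in range(blocks):
            pre = f"{side}{b}"
            for nm in ("q", "k", "v"):
                w(f"{pre}_self_{nm}", (d, inner), d**-0.5)
            w(f"{pre}_self_o", (inner, d), inner**-0.5)
            p[f"{pre}_norm1"] = parameter(np.ones(d))
            if side == "dec":
                for nm in ("q", "k", "v"):
                    w(f"{pre}_cross_{nm}", (d, inner), d**-0.5)
                w(f"{pre}_cross_o", (inner, d), inner**-0.5)
                p[f"{pre}_normx"] = parameter(np.ones(d))
            w(f"{pre}_ffn_in", (d, f), d**-0.5)
            w(f"{pre}_ffn_out", (f, d), f**-0.5)
            p[f"{pre}_norm2"] = parameter(np.ones(d))
    p["enc_norm_final"] = parameter(np.ones(d))
    p["dec_norm_final"] = parameter(np.ones(d))
    return p


def _rmsnorm(x: Tensor, g: Tensor) -> Tensor:
    var = (x * x).mean(axis=-1, keepdims=True)
    return x * (var + 1e-6) ** -0.5 * g


class _Forward:
    """Forward pass over a parameter dict; dropout only when training."""

    def __init__(self, cfg: ModelConfig, params: dict[str, Tensor],
                 train: bool = False, rng: Optional[np.random.Generator] = None):
        self.cfg = cfg
        self.p = params
        self.train = train and cfg.dropout > 0
        self.rng = rng

    def _drop(self, x: Tensor) -> Tensor:
        if not self.train:
            return x
        keep = 1.0 - self.cfg.dropout
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * constant(mask)

    def _attn(self, pre: str, kind: str, q_in: Tensor, kv_in: Tensor,
              bias: Optional[np.ndarray], mask: Optional[np.ndarray]) -> Tensor:
        cfg, p = self.cfg, self.p
        h, dh = cfg.heads, cfg.head_dim
        Bq, Tq, _ = q_in.shape
        Tk = kv_in.shape[1]
        q = (q_in @ p[f"{pre}_{kind}_q"]).reshape(Bq, Tq, h, dh).transpose(0, 2, 1, 3)
        k = (kv_in @ p[f"{pre}_{kind}_k"]).reshape(Bq, Tk, h, dh).transpose(0, 2, 1, 3)
        v = (kv_in @ p[f"{pre}_{kind}_v"]).reshape(Bq, Tk, h, dh).transpose(0, 2, 1, 3)
        logits = q @ k.transpose(0, 1, 3, 2) * (dh**-0.5)
        if bias is not None:
            logits = logits + bias  # (1,h,Tq,Tk) broadcast
        if mask is not None:
            logits = logits + constant(mask)
        att = logits.softmax()
        out = (att @ v).transpose(0, 2, 1, 3).reshape(Bq, Tq, h * dh)
        return self._drop(out @ p[f"{pre}_{kind}_o"])

    def _rel_bias(self, side: str, qlen: int, klen: int, causal: bool) -> Tensor:
        cfg = self.cfg
        buckets = _relative_buckets(qlen, klen, cfg.rel_buckets, cfg.rel_max_distance, causal)
        emb = self.p[f"{side}_relbias"].take_rows(buckets)  # (Tq,Tk,h)
        return emb.transpose(2, 0, 1).reshape(1, cfg.heads, qlen, klen)

    def encode(self, src_ids: np.ndarray, src_mask: np.ndarray) -> Tensor:
        p, cfg = self.p, self.cfg
        x = self._drop(p["embed"].take_rows(src_ids))
        bias = self._rel_bias("enc", src_ids.shape[1], src_ids.shape[1], causal=False)
        pad = (1.0 - src_mask[:, None, None, :]) * -1e9
        for b in range(cfg.encoder_blocks):
            pre = f"enc{b}"
            x = x + self._attn(pre, "self", _rmsnorm(x, p[f"{pre}_norm1"]),
                               _rmsnorm(x, p[f"{pre}_norm1"]), bias, pad)
            hidden = (_rmsnorm(x, p[f"{pre}_norm2"]) @ p[f"{pre}_ffn_in"]).relu()
            x = x + self._drop(hidden @ p[f"{pre}_ffn_out"])
        return _rmsnorm(x, p["enc_norm_final"])

    def decode(self, tgt_ids: np.ndarray, memory: Tensor, src_mask: np.ndarray) -> Tensor:
        p, cfg = self.p, self.cfg
        B, T = tgt_ids.shape
        x = self._drop(p["embed"].take_rows(tgt_ids))
        bias = self._rel_bias("dec", T, T, causal=True)
        causal = np.triu(np.full((T, T), -1e9), k=1)[None, None]
        pad = (1.0 - src_mask[:, None, None, :]) * -1e9
        for b in range(cfg.decoder_blocks):
            pre = f"dec{b}"
            nx = _rmsnorm(x, p[f"{pre}_norm1"])
            x = x + self._attn(pre, "self", nx, nx, bias, causal)
            x = x + self._attn(pre, "cross", _rmsnorm(x, p[f"{pre}_normx"]), memory, None, pad)
            hidden = (_rmsnorm(x, p[f"{pre}_norm2"]) @ p[f"{pre}_ffn_in"]).relu()
            x = x + self._drop(hidden @ p[f"{pre}_ffn_out"])
        x = _rmsnorm(x, p["dec_norm_final"])
        return x @ p["embed"].transpose(1, 0)  # tied output projection


# ---------------------------------------------------------------------------
# training


@dataclass
class Checkpoint:
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    vocab: Vocabulary
    params: dict[str, np.ndarray]
    loss_history: list[float] = field(default_factory=list)

    def save(self, directory: "str | Path") -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(
            json.dumps(
                {"model": asdict(self.model_cfg), "train": asdict(self.train_cfg)},
                sort_keys=True,
                indent=1,
            )
        )
        (d / "vocab.json").write_text(self.vocab.to_json())
        np.savez(d / "weights.npz", **self.params)
        (d / "losses.json").write_text(json.dumps(self.loss_history))
        return d

    @classmethod
    def load(cls, directory: "str | Path") -> "Checkpoint":
        d = Path(directory)
        cfg = json.loads((d / "config.json").read_text())
        with np.load(d / "weights.npz") as z:
            params = {k: z[k] for k in z.files}
        return cls(
            model_cfg=ModelConfig(**cfg["model"]),
            train_cfg=TrainConfig(**cfg["train"]),
            vocab=Vocabulary.from_json((d / "vocab.json").read_text()),
            params=params,
            loss_history=json.loads((d / "losses.json").read_text()),
        )


def _encode_batch(
    vocab: Vocabulary, examples: Sequence[TrainingExample], context_len: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    start, end = vocab.token_to_id[START], vocab.token_to_id[END]
    srcs = [vocab.encode(ex.input)[:context_len] for ex in examples]
    tgts = [[start] + vocab.encode(ex.target)[: context_len - 2] + [end] for ex in examples]
    smax = max(len(s) for s in srcs)
    tmax = max(len(t) for t in tgts)
    B = len(examples)
    src = np.zeros((B, smax), dtype=np.int64)
    smask = np.zeros((B, smax))
    tin = np.zeros((B, tmax - 1), dtype=np.int64)
    tout = np.zeros((B, tmax - 1), dtype=np.int64)
    tmask = np.zeros((B, tmax - 1))
    for i, (s, t) in enumerate(zip(srcs, tgts)):
        src[i, : len(s)] = s
        smask[i, : len(s)] = 1.0
        tin[i, : len(t) - 1] = t[:-1]
        tout[i, : len(t) - 1] = t[1:]
        tmask[i, : len(t) - 1] = 1.0
    return src, smask, tin, tout, tmask


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    corpus: Sequence[TrainingExample],
    steps: int,
    vocab: Optional[Vocabulary] = None,
    callback: Optional[Callable[[int, float], None]] = None,
) -> Checkpoint:
    """Train with AdamW under the warmup + stepwise-decay schedule.

    Fully seeded; aborts with a diagnostic on divergence (NaN loss).
    """
    if not corpus:
        raise ValueError("empty corpus")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    vocab = vocab or build_vocab(corpus)
    rng = np.random.default_rng(train_cfg.seed)
    params = _init_params(model_cfg, len(vocab), rng)
    m = {k: np.zeros_like(v.data) for k, v in params.items()}
    v2 = {k: np.zeros_like(v.data) for k, v in params.items()}
    losses: list[float] = []
    B = min(train_cfg.batch_size, len(corpus))
    for step in range(1, steps + 1):
        if len(corpus) <= B:
            batch = list(corpus)
        else:
            pick = rng.choice(len(corpus), size=B, replace=False)
            batch = [corpus[i] for i in pick]
        src, smask, tin, tout, tmask = _encode_batch(vocab, batch, model_cfg.context_len)
        fwd = _Forward(model_cfg, params, train=True, rng=rng)
        memory = fwd.encode(src, smask)
        logits = fwd.decode(tin, memory, smask)
        logp = logits.log_softmax()
        nll = -(logp.gather_last(tout) * constant(tmask)).sum() / max(tmask.sum(), 1.0)
        loss = float(nll.data)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at step {step}: loss={loss!r} "
                f"(peak_lr={train_cfg.peak_lr}, seed={train_cfg.seed})"
            )
        losses.append(loss)
        nll.backward()
        lr = learning_rate(train_cfg, step)
        b1, b2 = train_cfg.beta1, train_cfg.beta2
        for k, t in params.items():
            g = t.grad if t.grad is not None else np.zeros_like(t.data)
            m[k] = b1 * m[k] + (1 - b1) * g
            v2[k] = b2 * v2[k] + (1 - b2) * g * g
            mhat = m[k] / (1 - b1**step)
            vhat = v2[k] / (1 - b2**step)
            t.data -= lr * (mhat / (np.sqrt(vhat) + 1e-8) + train_cfg.weight_decay * t.data)
            t.grad = None
        if callback is not None:
            callback(step, loss)
    return Checkpoint(
        model_cfg=model_cfg,
        train_cfg=train_cfg,
        vocab=vocab,
        params={k: t.data.copy() for k, t in params.items()},
        loss_history=losses,
    )


def _live_params(ck: Checkpoint) -> dict[str, Tensor]:
    return {k: Tensor(v) for k, v in ck.params.items()}


def teacher_forced_accuracy(ck: Checkpoint, corpus: Sequence[TrainingExample]) -> float:
    """Fraction of (non-pad) target tokens predicted by argmax."""
    src, smask, tin, tout, tmask = _encode_batch(ck.vocab, corpus, ck.model_cfg.context_len)
    fwd = _Forward(ck.model_cfg, _live_params(ck))
    logits = fwd.decode(tin, fwd.encode(src, smask), smask).data
    pred = logits.argmax(axis=-1)
    hits = ((pred == tout) * tmask).sum()
    return float(hits / tmask.sum())


# ---------------------------------------------------------------------------
# beam search


def _default_canonical(text: str) -> str:
    """Canonical form for deduplication: edit-script text if it parses,
    else canonical SMILES if it parses, else the raw text."""
    from .chemgraph import MoleculeError, canonical_smiles
    from .ssredits import ScriptError, parse_script, script_text

    try:
        return script_text(parse_script(text))
    except ScriptError:
        pass
    try:
        return canonical_smiles(text.replace(" ", ""))
    except MoleculeError:
        return text


def beam_decode(
    ck: Checkpoint,
    input_tokens: "TokenSequence | Sequence[str]",
    beam_size: int = 10,
    max_len: Optional[int] = None,
    validator: Optional[Callable[[TokenSequence], bool]] = None,
    canonicalize: Callable[[str], str] = _default_canonical,
) -> list[Prediction]:
    """Length-normalized beam search with per-token confidences.

    Candidates are deduplicated by canonical decoded output; when a
    ``validator`` is given, candidates it rejects are dropped and ranks
    are refilled from the remaining beam.  ``beam_size=1`` is greedy
    decoding by construction.
    """
    if beam_size < 1:
        raise ValueError("beam_size must be >= 1")
    vocab = ck.vocab
    start, end, pad = (vocab.token_to_id[t] for t in (START, END, PAD))
    max_len = max_len or ck.model_cfg.context_len
    src_ids = np.array([vocab.encode(input_tokens)[: ck.model_cfg.context_len]])
    smask = np.ones_like(src_ids, dtype=np.float64)
    fwd = _Forward(ck.model_cfg, _live_params(ck))
    memory = fwd.encode(src_ids, smask)

    beams: list[tuple[list[int], list[float]]] = [([start], [])]
    finished: list[tuple[list[int], list[float]]] = []
    for _ in range(max_len):
        if not beams:
            break
        expansions: list[tuple[float, list[int], list[float]]] = []
        tin = np.full((len(beams), max(len(b[0]) for b in beams)), pad, dtype=np.int64)
        for i, (ids, _) in enumerate(beams):
            tin[i, : len(ids)] = ids
        probs = fwd.decode(tin, Tensor(np.repeat(memory.data, len(beams), 0)),
                           np.repeat(smask, len(beams), 0)).softmax().data
        for i, (ids, confs) in enumerate(beams):
            step_p = probs[i, len(ids) - 1]
            top = np.argsort(-step_p)[: beam_size + 1]
            for tok in top:
                if tok == pad:
                    continue
                conf = float(step_p[tok])
                if conf <= 0:
                    continue
                new_confs = confs + [conf]
                score = float(np.mean(np.log(new_confs)))
                expansions.append((score, ids + [int(tok)], new_confs))
        expansions.sort(key=lambda t: (-t[0], t[1]))
        # only the top beam_size expansions survive; END-terminated ones
        # among them move to the finished pool
        beams = []
        for score, ids, confs in expansions[: beam_size + len(finished)]:
            if ids[-1] == end:
                finished.append((ids, confs))
            elif len(beams) < beam_size:
                beams.append((ids, confs))
        if len(finished) >= 2 * beam_size:
            break

    # unfinished beams count as candidates too (score as-is)
    candidates = finished + beams
    scored = []
    for ids, confs in candidates:
        if ids and ids[-1] == end:
            body, body_confs = ids[1:-1], confs[:-1]
        else:
            body, body_confs = ids[1:], confs
        if not body_confs:
            continue
        toks = vocab.decode(body)
        scored.append((float(np.mean(np.log(body_confs))), toks, body_confs))
    scored.sort(key=lambda t: (-t[0], t[1]))

    out: list[Prediction] = []
    seen: set[str] = set()
    for score, toks, confs in scored:
        seq = TokenSequence(tuple(toks))
        key = canonicalize(" ".join(toks))
        if key in seen:
            continue
        if validator is not None and not validator(seq):
            continue
        seen.add(key)
        out.append(
            Prediction(
                tokens=seq,
                token_confidences=tuple(min(1.0, c) for c in confs),
                sequence_score=score,
                rank=len(out) + 1,
            )
        )
        if len(out) >= beam_size:
            break
    return out


def greedy_decode(ck: Checkpoint, input_tokens, max_len: Optional[int] = None) -> list[Prediction]:
    return beam_decode(ck, input_tokens, beam_size=1, max_len=max_len)
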