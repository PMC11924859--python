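"""Character-level generative language model of table cells, and the
row-merge classifier fine-tuned from it.

The language model is a decoder-only transformer (GPT): causal multi-head
self-attention, learned positional embeddings, pre-layer-norm blocks, and a
next-character cross-entropy objective over cell contents each terminated by
an ``<EOS>`` token.  The full-scale preset (6 layers, 6 heads, 384-d, 256
context) matches the published configuration; the tiny preset (2/2/64/64) is
for tests and desk-scale experiments.  The generative head is weight-tied to
the token embedding.

Row over-segmentation repair is cast as binary classification of vertically
neighboring cell contents: the input is ``upper <EOS> lower`` and the model
(the pretrained trunk with a single sigmoid head on the final position) says
whether the two strings are fragments of one cell.  :func:`merge_rows` applies
the classifier column-wise to neighboring physical rows and merges when the
mean column probability exceeds 0.5 (strictly).

Everything runs on numpy via :mod:`rte.nn`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .core_io import LogicalTable
from .nn import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "Vocab",
    "LMConfig",
    "TINY",
    "PAPER",
    "build_vocab",
    "TableLM",
    "pretrain_lm",
    "evaluate_nats_per_char",
    "encode_pair",
    "MergeClassifier",
    "finetune_merger",
    "score_pair",
    "merge_rows",
]

EOS = "<EOS>"


@dataclass(frozen=True)
class Vocab:
    """Code-point-sorted corpus characters plus the <EOS> sequence terminator."""

    chars: tuple[str, ...]
    eos_id: int

    @property
    def size(self) -> int:
        return len(self.chars) + 1

    def char_to_id(self, ch: str) -> int | None:
        i = self._index.get(ch)
        return i

    @property
    def _index(self) -> dict[str, int]:
        idx = getattr(self, "_idx_cache", None)
        if idx is None:
            idx = {c: i for i, c in enumerate(self.chars)}
            object.__setattr__(self, "_idx_cache", idx)
        return idx

    def encode(self, text: str) -> list[int]:
        """Map characters to ids; characters outside the vocabulary are dropped."""
        ids = []
        dropped = 0
        for ch in text:
            i = self._index.get(ch)
            if i is None:
                dropped += 1
            else:
                ids.append(i)
        if dropped:
            logger.debug("dropped %d out-of-vocabulary characters", dropped)
        return ids

    def decode(self, ids) -> str:
        return "".join(EOS if i == self.eos_id else self.chars[i] for i in ids)


def build_vocab(corpus) -> Vocab:
    """Distinct corpus characters (code-point sorted) plus <EOS>."""
    chars: set[str] = set()
    n = 0
    for cell in corpus:
        chars.update(cell)
        n += 1
    if n == 0:
        raise ValueError("empty corpus")
    ordered = tuple(sorted(chars))
    return Vocab(chars=ordered, eos_id=len(ordered))


@dataclass(frozen=True)
class LMConfig:
    n_layers: int = 6
    n_heads: int = 6
    d_model: int = 384
    context_len: int = 256

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.context_len < 2:
            raise ValueError("context_len must be >= 2")

    @property
    def d_ff(self) -> int:
        return 4 * self.d_model


PAPER = LMConfig(6, 6, 384, 256)
TINY = LMConfig(2, 2, 64, 64)


class TableLM:
    """Decoder-only character transformer with a tied generative head."""

    def __init__(self, vocab: Vocab, config: LMConfig = TINY, seed: int = 0):
        self.vocab = vocab
        self.config = config
        rng = nn.seeded_rng(seed)
        D, L, V = config.d_model, config.context_len, vocab.size

        def p(shape, std=0.02):
            return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)

        self.tok_emb = p((V, D))
        self.pos_emb = p((L, D))
        self.blocks = []
        proj_std = 0.02 / math.sqrt(2 * config.n_layers)
        for _ in range(config.n_layers):
            self.blocks.append(
                {
                    "ln1_g": Tensor(np.ones(D), requires_grad=True),
                    "ln1_b": Tensor(np.zeros(D), requires_grad=True),
                    "w_qkv": p((D, 3 * D)),
                    "b_qkv": Tensor(np.zeros(3 * D), requires_grad=True),
                    "w_proj": p((D, D), std=proj_std),
                    "b_proj": Tensor(np.zeros(D), requires_grad=True),
                    "ln2_g": Tensor(np.ones(D), requires_grad=True),
                    "ln2_b": Tensor(np.zeros(D), requires_grad=True),
                    "w_fc": p((D, config.d_ff)),
                    "b_fc": Tensor(np.zeros(config.d_ff), requires_grad=True),
                    "w_out": p((config.d_ff, D), std=proj_std),
                    "b_out": Tensor(np.zeros(D), requires_grad=True),
                }
            )
        self.lnf_g = Tensor(np.ones(D), requires_grad=True)
        self.lnf_b = Tensor(np.zeros(D), requires_grad=True)
        self._mask_cache: dict[int, np.ndarray] = {}

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = [self.tok_emb, self.pos_emb, self.lnf_g, self.lnf_b]
        for blk in self.blocks:
            params.extend(blk.values())
        return params

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward --------------------------------------------------------------
    def _causal_mask(self, t: int) -> np.ndarray:
        m = self._mask_cache.get(t)
        if m is None:
            m = np.triu(np.full((t, t), -1e9, dtype=np.float32), k=1)
            self._mask_cache[t] = m
        return m

    def encode(self, ids: np.ndarray) -> Tensor:
        """Final-layer-norm hidden states, shape (B, T, D)."""
        cfg = self.config
        B, T = ids.shape
        if T > cfg.context_len:
            raise ValueError(f"sequence length {T} exceeds context {cfg.context_len}")
        H, D = cfg.n_heads, cfg.d_model
        dh = D // H
        x = nn.embedding(self.tok_emb, ids) + nn.embedding(self.pos_emb, np.arange(T))
        mask = self._causal_mask(T)
        for blk in self.blocks:
            h = nn.layernorm(x, blk["ln1_g"], blk["ln1_b"])
            qkv = h.matmul(blk["w_qkv"]) + blk["b_qkv"]
            q = qkv.narrow(2, 0, D).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            k = qkv.narrow(2, D, D).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            v = qkv.narrow(2, 2 * D, D).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            att = nn.add_mask(q.matmul(k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh)), mask)
            out = att.softmax().matmul(v).transpose(0, 2, 1, 3).reshape(B, T, D)
            x = x + (out.matmul(blk["w_proj"]) + blk["b_proj"])
            h2 = nn.layernorm(x, blk["ln2_g"], blk["ln2_b"])
            mlp = (h2.matmul(blk["w_fc"]) + blk["b_fc"]).gelu()
            x = x + (mlp.matmul(blk["w_out"]) + blk["b_out"])
        return nn.layernorm(x, self.lnf_g, self.lnf_b)

    def logits(self, ids: np.ndarray) -> Tensor:
        """Next-character logits (B, T, V); head tied to the token embedding."""
        h = self.encode(ids)
        return h.matmul(self.tok_emb.transpose(1, 0))

    def loss(self, ids: np.ndarray, targets: np.ndarray) -> Tensor:
        B, T = ids.shape
        lg = self.logits(ids).reshape(B * T, self.vocab.size)
        return nn.cross_entropy_logits(lg, targets.reshape(B * T))

    # -- persistence ------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrs = {"tok_emb": self.tok_emb.data, "pos_emb": self.pos_emb.data,
                "lnf_g": self.lnf_g.data, "lnf_b": self.lnf_b.data}
        for i, blk in enumerate(self.blocks):
            for k, t in blk.items():
                arrs[f"blk{i}.{k}"] = t.data
        return arrs

    def save(self, path) -> None:
        meta = json.dumps(
            {
                "chars": list(self.vocab.chars),
                "config": [self.config.n_layers, self.config.n_heads,
                           self.config.d_model, self.config.context_len],
            }
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode("utf-8"), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path) -> "TableLM":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        vocab = Vocab(chars=tuple(meta["chars"]), eos_id=len(meta["chars"]))
        model = cls(vocab, LMConfig(*meta["config"]))
        model.load_arrays(data)
        return model

    def load_arrays(self, data) -> None:
        self.tok_emb.data = np.asarray(data["tok_emb"], dtype=np.float32)
        self.pos_emb.data = np.asarray(data["pos_emb"], dtype=np.float32)
        self.lnf_g.data = np.asarray(data["lnf_g"], dtype=np.float32)
        self.lnf_b.data = np.asarray(data["lnf_b"], dtype=np.float32)
        for i, blk in enumerate(self.blocks):
            for k in blk:
                blk[k].data = np.asarray(data[f"blk{i}.{k}"], dtype=np.float32)


# ---------------------------------------------------------------------------
# pre-training
# ---------------------------------------------------------------------------


def _corpus_stream(corpus, vocab: Vocab) -> np.ndarray:
    ids: list[int] = []
    for cell in corpus:
        ids.extend(vocab.encode(cell))
        ids.append(vocab.eos_id)
    return np.asarray(ids, dtype=np.int64)


def pretrain_lm(
    corpus,
    config: LMConfig = TINY,
    seed: int = 0,
    steps: int = 1000,
    lr: float = 1e-3,
    batch_size: int = 16,
    vocab: Vocab | None = None,
) -> tuple[TableLM, list[float]]:
    """Train the next-character objective on cell contents.

    Cells are terminated by <EOS> and concatenated into a stream from which
    random ``context_len``-character windows are drawn each step.  Returns the
    model and the per-step training-loss trace.  Deterministic given the seed.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    corpus = list(corpus)
    vocab = vocab or build_vocab(corpus)
    stream = _corpus_stream(corpus, vocab)
    L = config.context_len
    if stream.size < L + 1:
        reps = (L + 1) // max(1, stream.size) + 1
        stream = np.tile(stream, reps)
    if stream.size < L + 1:
        raise ValueError("corpus too small to pack a single training window")

    model = TableLM(vocab, config, seed=seed)
    rng = nn.seeded_rng(seed + 1)
    opt = nn.Adam(model.parameters(), lr=lr)
    losses: list[float] = []
    for _ in range(steps):
        starts = rng.integers(0, stream.size - L, size=batch_size)
        x = np.stack([stream[s : s + L] for s in starts])
        y = np.stack([stream[s + 1 : s + L + 1] for s in starts])
        loss = model.loss(x, y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return model, losses


def evaluate_nats_per_char(model: TableLM, corpus, stride: int | None = None) -> float:
    """Mean next-character loss over the corpus with sliding full-context windows.

    Windows advance by ``stride`` (default half the context); only the fresh
    positions of each window are scored, so every character after the first
    window is predicted with at least half a context of history.
    """
    vocab = model.vocab
    stream = _corpus_stream(corpus, vocab)
    n = stream.size
    L = model.config.context_len
    stride = stride or max(1, L // 2)
    total, count = 0.0, 0
    s = 0
    while s < n - 1:
        x = stream[s : s + L][None, :]
        y = stream[s + 1 : s + x.shape[1] + 1]
        lg = model.logits(x).data[0, : y.size]
        z = lg - lg.max(axis=-1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
        nll = -logp[np.arange(y.size), y]
        lo = 0 if s == 0 else L - stride
        if lo < y.size:
            total += float(nll[lo:].sum())
            count += int(y.size - lo)
        if s + L >= n - 1:
            break
        s += stride
    return total / max(count, 1)


# ---------------------------------------------------------------------------
# merge classification
# ---------------------------------------------------------------------------


def encode_pair(upper: str, lower: str, vocab: Vocab, context_len: int) -> list[int]:
    """ids of ``upper <EOS> lower``, truncated around the <EOS> boundary.

    When too long, the last floor((L-1)/2) characters of the upper cell and
    the first remaining-budget characters of the lower cell are kept, so the
    boundary the classifier reads is always present.
    """
    if context_len < 3:
        raise ValueError("context_len must be >= 3")
    up = vocab.encode(upper)
    low = vocab.encode(lower)
    if len(up) + 1 + len(low) <= context_len:
        return up + [vocab.eos_id] + low
    keep_up = min(len(up), (context_len - 1) // 2)
    budget_low = context_len - 1 - keep_up
    return up[len(up) - keep_up :] + [vocab.eos_id] + low[:budget_low]


class MergeClassifier:
    """Pretrained LM trunk with a single sigmoid head on the final position."""

    def __init__(self, lm: TableLM, seed: int = 0):
        self.lm = lm
        rng = nn.seeded_rng(seed + 17)
        D = lm.config.d_model
        self.w_head = Tensor(rng.normal(0.0, 0.02, size=(D, 1)), requires_grad=True)
        self.b_head = Tensor(np.zeros(1), requires_grad=True)
        self.threshold = 0.5

    def parameters(self) -> list[Tensor]:
        return self.lm.parameters() + [self.w_head, self.b_head]

    def _batch_logits(self, seqs: list[list[int]]) -> Tensor:
        maxlen = max(len(s) for s in seqs)
        pad = self.lm.vocab.eos_id  # positions past each final index are never read
        ids = np.full((len(seqs), maxlen), pad, dtype=np.int64)
        last = np.empty(len(seqs), dtype=np.int64)
        for r, s in enumerate(seqs):
            ids[r, : len(s)] = s
            last[r] = len(s) - 1
        h = self.lm.encode(ids)
        final = nn.take_positions(h, last)
        return final.matmul(self.w_head) + self.b_head

    def score_pairs(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        """Merge probabilities for (upper, lower) pairs, batched."""
        seqs = [
            encode_pair(u, l, self.lm.vocab, self.lm.config.context_len) or [self.lm.vocab.eos_id]
            for u, l in pairs
        ]
        logits = self._batch_logits(seqs).data.reshape(-1)
        return 1.0 / (1.0 + np.exp(-logits))

    def score_pair(self, upper: str, lower: str) -> float:
        return float(self.score_pairs([(upper, lower)])[0])

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        meta = json.dumps(
            {
                "chars": list(self.lm.vocab.chars),
                "config": [self.lm.config.n_layers, self.lm.config.n_heads,
                           self.lm.config.d_model, self.lm.config.context_len],
            }
        )
        np.savez(
            path,
            __meta__=np.frombuffer(meta.encode("utf-8"), dtype=np.uint8),
            w_head=self.w_head.data,
            b_head=self.b_head.data,
            **self.lm.state_arrays(),
        )

    @classmethod
    def load(cls, path) -> "MergeClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        vocab = Vocab(chars=tuple(meta["chars"]), eos_id=len(meta["chars"]))
        lm = TableLM(vocab, LMConfig(*meta["config"]))
        lm.load_arrays(data)
        clf = cls(lm)
        clf.w_head.data = np.asarray(data["w_head"], dtype=np.float32)
        clf.b_head.data = np.asarray(data["b_head"], dtype=np.float32)
        return clf


def finetune_merger(
    lm: TableLM,
    instances,
    epochs: int = 2,
    lr: float = 2e-4,
    seed: int = 0,
    batch_size: int = 32,
) -> MergeClassifier:
    """Fine-tune the LM trunk plus a fresh sigmoid head on merge instances.

    Adam, two epochs at learning rate 2e-4 by default.  Deterministic given
    the seed; requires both classes present.
    """
    instances = list(instances)
    labels = {inst.label for inst in instances}
    if labels != {0, 1}:
        raise ValueError("need both positive and negative instances")
    clf = MergeClassifier(lm, seed=seed)
    opt = nn.Adam(clf.parameters(), lr=lr)
    rng = nn.seeded_rng(seed + 31)
    idx = np.arange(len(instances))
    L = lm.config.context_len
    for _ in range(max(0, epochs)):
        rng.shuffle(idx)
        for s in range(0, len(idx), batch_size):
            batch = [instances[k] for k in idx[s : s + batch_size]]
            seqs = [encode_pair(b.upper, b.lower, lm.vocab, L) or [lm.vocab.eos_id] for b in batch]
            y = np.array([b.label for b in batch], dtype=np.float32)
            logits = clf._batch_logits(seqs).reshape(len(batch))
            loss = nn.bce_logits(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
    return clf


def score_pair(clf: MergeClassifier, upper: str, lower: str) -> float:
    """Merge probability for one neighboring-cell pair (deterministic)."""
    return clf.score_pair(upper, lower)


# ---------------------------------------------------------------------------
# max-voting row merge
# ---------------------------------------------------------------------------


def merge_rows(grid: LogicalTable, clf, vote_threshold: float = 0.5) -> LogicalTable:
    """Merge neighboring physical rows by mean column merge probability.

    Scans top-down; for the current row group versus the next physical row,
    every column pair with BOTH cells non-empty is scored (empty-cell pairs
    are out of the classifier's training distribution and are excluded from
    the vote; if every pair is excluded the rows are not merged).  The row is
    merged when the mean probability strictly exceeds the threshold; merged
    cells are joined with a single space and the merged group becomes the new
    upper row.  ``clf`` needs only a ``score_pair``/``score_pairs`` method.
    """
    if grid.n_rows == 0:
        return LogicalTable(cells=[], n_header_rows=grid.n_header_rows)
    out_rows: list[list[str]] = [list(grid.cells[0])]
    for r in range(1, grid.n_rows):
        lower = grid.cells[r]
        upper = out_rows[-1]
        pairs = [
            (upper[j], lower[j])
            for j in range(grid.n_cols)
            if upper[j] and lower[j]
        ]
        if pairs:
            if hasattr(clf, "score_pairs"):
                probs = np.asarray(clf.score_pairs(pairs), dtype=float)
            else:
                probs = np.array([clf.score_pair(u, l) for u, l in pairs], dtype=float)
            score = float(probs.mean())
        else:
            score = 0.0
        if score > vote_threshold:
            out_rows[-1] = [
                (f"{u} {l}" if u and l else (u or l)) for u, l in zip(upper, lower)
            ]
        else:
            out_rows.append(list(lower))
    return LogicalTable(cells=out_rows, n_header_rows=grid.n_header_rows)
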