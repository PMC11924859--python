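"""Two-level stacked generalizer flagging pages that contain resource tables.

Level 1 is a recurrent (LSTM) classifier over the tokens of each text line
plus a context window of previous lines, static word embeddings, and binary
indicators for horizontal/vertical rules touching the line; positive-class
errors are up-weighted 50x to counter the scarcity of in-table lines.  Level
2 is a linear SVM over the page's TF-IDF bag of words, augmented with the
number of in-table lines level 1 predicted on the page (positive-class
weight 5).  A page is a candidate when level 2 says so; only candidates are
passed to the expensive table detector downstream.

Embeddings are pluggable: any word->vector text file, or a seeded random
table for self-contained experiments.
"""

from __future__ import annotations

import pickle
import re
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.svm import LinearSVC

from . import nn
from .core_io import PageRecord
from .nn import Tensor
from .reconstruct import build_text_lines

__all__ = [
    "tokenize",
    "EmbeddingTable",
    "page_lines",
    "LineFeatures",
    "extract_line_features",
    "LineModel",
    "train_line_classifier",
    "predict_in_table_lines",
    "PageModel",
    "train_page_classifier",
    "detect_candidate_pages",
]

_TOKEN_RE = re.compile(r"[a-z]+|[0-9]+|[^\sa-z0-9]")
NUM_TOKEN = "<NUM>"


def tokenize(text: str) -> list[str]:
    """Lowercase, split at whitespace/punctuation; digit runs become <NUM>."""
    return [NUM_TOKEN if t.isdigit() else t for t in _TOKEN_RE.findall(text.lower())]


class EmbeddingTable:
    """Static word -> vector map with a designated out-of-vocabulary vector."""

    def __init__(self, vectors: dict[str, np.ndarray], dim: int):
        self.vectors = vectors
        self.dim = dim
        self.oov = np.zeros(dim, dtype=np.float32)
        self.null = np.zeros(dim, dtype=np.float32)  # padding token at page starts

    @classmethod
    def random(cls, vocab, dim: int = 50, seed: int = 0) -> "EmbeddingTable":
        """Seeded random embeddings — a self-contained stand-in for trained ones."""
        rng = nn.seeded_rng(seed)
        vecs = {
            w: (rng.standard_normal(dim) / np.sqrt(dim)).astype(np.float32)
            for w in sorted(set(vocab))
        }
        return cls(vecs, dim)

    @classmethod
    def from_text_file(cls, path) -> "EmbeddingTable":
        """Read a GloVe-style text file: token followed by its components."""
        vecs: dict[str, np.ndarray] = {}
        dim = None
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) < 2:
                    continue
                v = np.asarray([float(x) for x in parts[1:]], dtype=np.float32)
                dim = dim or v.size
                vecs[parts[0]] = v
        if not vecs:
            raise ValueError(f"{path}: no embeddings found")
        return cls(vecs, dim)

    def get(self, token: str) -> np.ndarray:
        return self.vectors.get(token, self.oov)


@dataclass
class PageLine:
    """One visual text line: band-joined segments plus its vertical band."""

    text: str
    y_min: float
    y_max: float


def page_lines(page: PageRecord) -> list[PageLine]:
    """Visual lines of a page: text-line segments grouped by band, x-ordered."""
    lines = build_text_lines(page)
    bands: dict[int, list] = {}
    for l in lines:
        bands.setdefault(l.band_index, []).append(l)
    out = []
    for b in sorted(bands, key=lambda b: min(l.y_top for l in bands[b])):
        segs = sorted(bands[b], key=lambda l: l.x_min)
        out.append(
            PageLine(
                text=" ".join(s.text for s in segs),
                y_min=min(s.y_min for s in segs),
                y_max=max(s.y_max for s in segs),
            )
        )
    return out


def _graphics_indicators(page: PageRecord, line: PageLine) -> tuple[int, int]:
    h = v = 0
    for gl in page.graphics:
        if gl.orientation == "horizontal":
            if line.y_min - 2 <= gl.y_min <= line.y_max + 2:
                h = 1
        else:
            if gl.y_min <= line.y_max and gl.y_max >= line.y_min:
                v = 1
    return h, v


@dataclass
class LineFeatures:
    """Window of token vectors plus structural indicators for one line."""

    token_vectors: np.ndarray  # (T, dim)
    indicators: np.ndarray  # (4,) h/v current, h/v previous
    page_number: int


def extract_line_features(
    page: PageRecord,
    line_index: int,
    embeddings: EmbeddingTable,
    window: int = 2,
    lines: list[PageLine] | None = None,
    max_tokens: int = 40,
) -> LineFeatures:
    """Features for one visual line: its tokens plus up to ``window`` previous
    lines' tokens (null-padded at the page start), embedded; indicator bits
    for rules crossing the current and previous line."""
    lines = lines if lines is not None else page_lines(page)
    if not 0 <= line_index < len(lines):
        raise IndexError(f"line index {line_index} out of range ({len(lines)} lines)")
    vecs: list[np.ndarray] = []
    for k in range(line_index - window, line_index + 1):
        if k < 0:
            vecs.append(embeddings.null)
            continue
        toks = tokenize(lines[k].text)
        vecs.extend(embeddings.get(t) for t in toks)
    if not vecs:
        vecs.append(embeddings.null)
    h_cur, v_cur = _graphics_indicators(page, lines[line_index])
    h_prev = v_prev = 0
    if line_index > 0:
        h_prev, v_prev = _graphics_indicators(page, lines[line_index - 1])
    tv = np.stack(vecs[-max_tokens:]).astype(np.float32)
    return LineFeatures(
        token_vectors=tv,
        indicators=np.array([h_cur, v_cur, h_prev, v_prev], dtype=np.float32),
        page_number=page.page_index,
    )


# ---------------------------------------------------------------------------
# level 1: recurrent line classifier
# ---------------------------------------------------------------------------


class LineModel:
    """Single-layer LSTM over token embeddings, indicators concatenated
    before a logistic output."""

    def __init__(self, input_dim: int, hidden: int = 64, seed: int = 0, window: int = 2):
        rng = nn.seeded_rng(seed)
        self.input_dim = input_dim
        self.hidden = hidden
        self.window = window
        s = 1.0 / np.sqrt(hidden)
        self.w_x = Tensor(rng.uniform(-s, s, size=(input_dim, 4 * hidden)), requires_grad=True)
        self.w_h = Tensor(rng.uniform(-s, s, size=(hidden, 4 * hidden)), requires_grad=True)
        self.b = Tensor(np.zeros(4 * hidden), requires_grad=True)
        self.w_out = Tensor(rng.uniform(-s, s, size=(hidden + 5, 1)), requires_grad=True)
        self.b_out = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.w_x, self.w_h, self.b, self.w_out, self.b_out]

    def logit(self, feats: LineFeatures) -> Tensor:
        H = self.hidden
        h = Tensor(np.zeros((1, H)))
        c = Tensor(np.zeros((1, H)))
        for t in range(feats.token_vectors.shape[0]):
            x = Tensor(feats.token_vectors[t][None, :])
            z = x.matmul(self.w_x) + h.matmul(self.w_h) + self.b
            i = z.narrow(1, 0, H).sigmoid()
            f = z.narrow(1, H, H).sigmoid()
            g = z.narrow(1, 2 * H, H).tanh()
            o = z.narrow(1, 3 * H, H).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        extra = np.concatenate([feats.indicators, [feats.page_number / 100.0]]).astype(np.float32)
        feat = nn.concat([h, Tensor(extra[None, :])], axis=1)
        return feat.matmul(self.w_out) + self.b_out

    def predict_proba(self, feats: LineFeatures) -> float:
        z = float(self.logit(feats).data.reshape(()))
        return 1.0 / (1.0 + np.exp(-z))


def train_line_classifier(
    dataset: list[tuple[LineFeatures, int]],
    class_weight_pos: float = 50.0,
    seed: int = 0,
    hidden: int = 64,
    epochs: int = 3,
    lr: float = 5e-3,
) -> tuple[LineModel, list[float]]:
    """Train the level-1 line classifier with up-weighted positive errors.

    Deterministic given the seed; returns the model and per-sample loss trace.
    """
    if not dataset:
        raise ValueError("empty dataset")
    labels = {y for _, y in dataset}
    if labels != {0, 1}:
        raise ValueError("need both in-table and out-of-table lines")
    dim = dataset[0][0].token_vectors.shape[1]
    model = LineModel(dim, hidden=hidden, seed=seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    rng = nn.seeded_rng(seed + 7)
    order = np.arange(len(dataset))
    losses: list[float] = []
    for _ in range(epochs):
        rng.shuffle(order)
        for k in order:
            feats, y = dataset[k]
            logit = model.logit(feats).reshape(1)
            loss = nn.bce_logits(logit, np.array([y], dtype=np.float32), pos_weight=class_weight_pos)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
    return model, losses


def predict_in_table_lines(
    model: LineModel, page: PageRecord, embeddings: EmbeddingTable
) -> int:
    """Number of lines on the page whose predicted in-table probability > 0.5."""
    lines = page_lines(page)
    count = 0
    for k in range(len(lines)):
        feats = extract_line_features(page, k, embeddings, window=model.window, lines=lines)
        if model.predict_proba(feats) > 0.5:
            count += 1
    return count


# ---------------------------------------------------------------------------
# level 2: TF-IDF + linear SVM page classifier
# ---------------------------------------------------------------------------


def page_text(page: PageRecord) -> str:
    return " ".join(l.text for l in page_lines(page))


class PageModel:
    """TF-IDF bag of words plus the level-1 in-table line count, linear SVM."""

    def __init__(self, vectorizer: TfidfVectorizer, svm: LinearSVC):
        self.vectorizer = vectorizer
        self.svm = svm

    def _features(self, texts: list[str], counts: list[int]):
        X = self.vectorizer.transform(texts)
        c = np.asarray(counts, dtype=np.float64).reshape(-1, 1)
        return sparse.hstack([X, sparse.csr_matrix(c)], format="csr")

    def predict(self, texts: list[str], counts: list[int]) -> np.ndarray:
        return self.svm.predict(self._features(texts, counts))

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "PageModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def train_page_classifier(
    texts: list[str],
    counts: list[int],
    labels: list[int],
    class_weight_pos: float = 5.0,
    seed: int = 0,
    C: float = 1.0,
) -> PageModel:
    """Fit the level-2 linear max-margin page classifier.

    TF-IDF uses natural term frequency, smoothed idf, and L2 normalization
    over the training-corpus vocabulary; positive-class errors are penalized
    ``class_weight_pos`` times more.
    """
    if len(set(labels)) < 2:
        raise ValueError("need both classes to train the page classifier")
    vectorizer = TfidfVectorizer(tokenizer=tokenize, token_pattern=None, norm="l2", smooth_idf=True)
    vectorizer.fit(texts)
    svm = LinearSVC(C=C, class_weight={0: 1.0, 1: class_weight_pos}, random_state=seed)
    model = PageModel(vectorizer, svm)
    X = model._features(texts, counts)
    svm.fit(X, np.asarray(labels))
    return model


@dataclass
class PageDetector:
    """The trained two-level ensemble bundled with its embeddings."""

    line_model: LineModel
    page_model: PageModel
    embeddings: EmbeddingTable

    def detect(self, doc: list[PageRecord]) -> list[int]:
        return detect_candidate_pages(doc, self.line_model, self.page_model, self.embeddings)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "PageDetector":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a PageDetector")
        return obj


def detect_candidate_pages(
    doc: list[PageRecord],
    line_model: LineModel,
    page_model: PageModel,
    embeddings: EmbeddingTable,
) -> list[int]:
    """Stacked prediction: level-1 in-table line counts feed the page SVM.

    Returns the sorted indices of pages classified as resource-table
    candidates.
    """
    if not doc:
        return []
    texts = [page_text(p) for p in doc]
    counts = [predict_in_table_lines(line_model, p, embeddings) for p in doc]
    preds = page_model.predict(texts, counts)
    return sorted(p.page_index for p, y in zip(doc, preds) if y == 1)
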