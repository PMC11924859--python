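"""End-to-end orchestration of the four reconstruction pipelines.

All variants share the candidate-page detection front end (optional: when no
page-detector model is supplied, every page with a table detection is
processed) and the detector-box ingestion; they differ in how the grid is
built:

* ``col`` — column ranges only, heuristic row merge (over-segmentation of
  wrapped cells persists);
* ``row`` — column and row ranges from the structure detections;
* ``lm``  — the column pipeline followed by language-model row merging;
* ``ocr`` — grid and text purely from the image modality.

Also provides the synthetic-fixture factory and the mode comparison used to
benchmark the variants against each other on seeded synthetic documents.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core_io import (
    DetectionRecord,
    LogicalTable,
    PageRecord,
    read_charboxes,
    read_detections,
)
from .grits import grits
from .ocr_adapter import CellImage, FakeOCREngine, reconstruct_table_ocr, synthesize_cell_images
from .page_detect import (
    EmbeddingTable,
    PageDetector,
    extract_line_features,
    page_lines,
    page_text,
    predict_in_table_lines,
    tokenize,
    train_line_classifier,
    train_page_classifier,
)
from .reconstruct import reconstruct_table
from .synth import (
    LayoutSpec,
    OverflowConfig,
    SyntheticDocument,
    generate_document,
    generate_resource_table,
    render_table,
    simulate_overflow,
)
from .table_lm import MergeClassifier, merge_rows

logger = logging.getLogger(__name__)

MODES = ("col", "row", "ocr", "lm")

__all__ = [
    "RunConfig",
    "run",
    "OverflowFixture",
    "make_overflow_fixture",
    "compare_modes",
    "synthetic_page_corpus",
    "line_dataset",
    "train_page_detector",
    "evaluate_page_detector",
]


@dataclass
class RunConfig:
    """One reconstruction run: mode, inputs, thresholds, and the seed."""

    mode: str
    charboxes: str | None = None
    detections: str | None = None
    detector_model: str | None = None  # PageDetector bundle (optional)
    classifier: str | None = None  # merge classifier, lm mode
    images: str | None = None  # crop directory, ocr mode
    pages: list[int] | None = None
    pad: float = 1.0
    rect_overlap: float = 0.70
    text_overlap: float = 0.50
    vote_threshold: float = 0.5
    seed: int = 0
    log_level: str = "WARNING"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML mapping of the same fields."""
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a YAML mapping of RunConfig fields")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.charboxes is None and self.mode != "ocr":
            raise ValueError("charboxes path is required")
        if self.detections is None:
            raise ValueError("detections path is required")
        if self.mode == "lm" and self.classifier is None:
            raise ValueError("lm mode requires a merge-classifier path")
        if self.mode == "ocr" and self.images is None:
            raise ValueError("ocr mode requires a cell-crop directory")


def _load_crops(images_dir: str) -> dict[tuple[int, int], CellImage]:
    import re

    from PIL import Image

    crops: dict[tuple[int, int], CellImage] = {}
    pat = re.compile(r"r(\d+)c(\d+)\.png$")
    for path in sorted(Path(images_dir).iterdir()):
        m = pat.search(path.name)
        if m:
            i, j = int(m.group(1)), int(m.group(2))
            crops[(i, j)] = CellImage(np.asarray(Image.open(path)), grid_pos=(i, j))
    return crops


def run(config: RunConfig) -> tuple[list[LogicalTable], dict]:
    """Execute one configured reconstruction; returns tables and a manifest."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.WARNING))
    detections = read_detections(config.detections)
    pages: list[PageRecord] = (
        read_charboxes(config.charboxes) if config.charboxes else []
    )

    if config.detector_model:
        detector = PageDetector.load(config.detector_model)
        candidates = set(detector.detect(pages))
        pages = [p for p in pages if p.page_index in candidates]
        detections = [d for d in detections if d.page_index in candidates]
    if config.pages is not None:
        keep = set(config.pages)
        pages = [p for p in pages if p.page_index in keep]
        detections = [d for d in detections if d.page_index in keep]

    if config.mode == "ocr":
        crops = _load_crops(config.images)
        table = reconstruct_table_ocr(detections, crops)
    else:
        table = reconstruct_table(
            detections, pages, mode="row" if config.mode == "row" else "col",
            pad=config.pad,
        )
        if config.mode == "lm":
            clf = MergeClassifier.load(config.classifier)
            table = merge_rows(table, clf, vote_threshold=config.vote_threshold)

    digest = hashlib.sha256(
        json.dumps(table.cells, ensure_ascii=False).encode("utf-8")
    ).hexdigest()
    manifest = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "thresholds": {
            "pad": config.pad,
            "rect_overlap": config.rect_overlap,
            "text_overlap": config.text_overlap,
            "vote_threshold": config.vote_threshold,
        },
        "n_tables": 1,
        "shape": [table.n_rows, table.n_cols],
        "sha256": digest,
    }
    return [table], manifest


# ---------------------------------------------------------------------------
# synthetic fixtures and mode comparison
# ---------------------------------------------------------------------------


@dataclass
class OverflowFixture:
    """A rendered synthetic table with everything each pipeline variant needs."""

    pages: list[PageRecord]
    detections: list[DetectionRecord]
    gold: LogicalTable
    overseg: LogicalTable
    gold_row_groups: list[list[int]]
    cell_images: dict[tuple[int, int], CellImage]
    seed: int


def make_overflow_fixture(
    seed: int,
    n_rows: int = 7,
    overflow: bool = True,
    layout: LayoutSpec = LayoutSpec(),
    cfg: OverflowConfig | None = None,
    superscript_prob: float = 0.0,
) -> OverflowFixture:
    """Render a seeded resource table, over-segmented when ``overflow``.

    The rendered physical grid is the over-segmented table; the gold target
    is the original logical table.
    """
    table = generate_resource_table(
        n_rows, seed, overflow=overflow, superscript_prob=superscript_prob
    )
    cfg = cfg or OverflowConfig(seed=seed)
    if overflow:
        overseg, groups, _ = simulate_overflow(table, cfg)
    else:
        overseg, groups = table, [[i] for i in range(table.n_rows)]
    pages, detections, _ = render_table(overseg, layout, rng_seed=seed)
    crops = synthesize_cell_images(overseg, rng_seed=seed)
    return OverflowFixture(
        pages=pages,
        detections=detections,
        gold=table,
        overseg=overseg,
        gold_row_groups=groups,
        cell_images=crops,
        seed=seed,
    )


def run_mode_on_fixture(
    fixture: OverflowFixture,
    mode: str,
    merge_scorer=None,
    ocr_engine=None,
) -> LogicalTable:
    """Run one pipeline variant on an in-memory fixture."""
    if mode == "ocr":
        return reconstruct_table_ocr(
            fixture.detections,
            fixture.cell_images,
            engine=ocr_engine or FakeOCREngine(),
            page_size=(fixture.pages[0].page_width, fixture.pages[0].page_height),
        )
    table = reconstruct_table(
        fixture.detections, fixture.pages, mode="row" if mode == "row" else "col"
    )
    if mode == "lm":
        if merge_scorer is None:
            raise ValueError("lm mode needs a merge scorer")
        table = merge_rows(table, merge_scorer)
    return table


def compare_modes(
    fixtures: list[OverflowFixture],
    modes=MODES,
    merge_scorer=None,
    ocr_engine=None,
    csv_path=None,
) -> dict[str, dict[str, float]]:
    """Mean GriTS (content and topology, with P and R) per mode over fixtures."""
    if not fixtures:
        raise ValueError("need at least one fixture")
    summary: dict[str, dict[str, float]] = {}
    for mode in modes:
        rows = []
        for fx in fixtures:
            pred = run_mode_on_fixture(fx, mode, merge_scorer=merge_scorer, ocr_engine=ocr_engine)
            c = grits(fx.gold, pred, "content")
            t = grits(fx.gold, pred, "topology")
            rows.append(c + t)
        arr = np.asarray(rows)
        m = arr.mean(axis=0)
        summary[mode] = {
            "grits_cont": float(m[0]),
            "grits_p_cont": float(m[1]),
            "grits_r_cont": float(m[2]),
            "grits_top": float(m[3]),
            "grits_p_top": float(m[4]),
            "grits_r_top": float(m[5]),
        }
    if csv_path:
        with open(csv_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            cols = ["mode", "grits_cont", "grits_p_cont", "grits_r_cont",
                    "grits_top", "grits_p_top", "grits_r_top"]
            writer.writerow(cols)
            for mode in modes:
                writer.writerow([mode] + [f"{summary[mode][c]:.4f}" for c in cols[1:]])
    return summary


# ---------------------------------------------------------------------------
# page-detector training on synthetic corpora
# ---------------------------------------------------------------------------


def synthetic_page_corpus(
    seed: int, n_docs: int = 10, table_prob: float = 0.5, n_pages: int = 3
) -> list[SyntheticDocument]:
    """Seeded corpus of documents, roughly half containing a resource table."""
    rng = np.random.default_rng(seed)
    docs = []
    for d in range(n_docs):
        has_table = rng.random() < table_prob if d >= 2 else bool(d % 2)
        table_page = int(rng.integers(0, n_pages)) if has_table else None
        docs.append(
            generate_document(
                int(rng.integers(0, 2**31)),
                n_pages=n_pages,
                table_page=table_page,
                table_rows=int(rng.integers(5, 9)),
            )
        )
    return docs


def _line_label(doc: SyntheticDocument, page: PageRecord, y_min: float, y_max: float) -> int:
    region = doc.table_regions.get(page.page_index)
    if region is None:
        return 0
    yc = 0.5 * (y_min + y_max)
    return int(region[0] - 1 <= yc <= region[1] + 1)


def line_dataset(docs: list[SyntheticDocument], embeddings: EmbeddingTable, window: int = 2):
    """(LineFeatures, in-table label) pairs over all pages of all documents."""
    data = []
    for doc in docs:
        for page in doc.pages:
            lines = page_lines(page)
            for k, line in enumerate(lines):
                feats = extract_line_features(page, k, embeddings, window=window, lines=lines)
                data.append((feats, _line_label(doc, page, line.y_min, line.y_max)))
    return data


def corpus_embeddings(docs: list[SyntheticDocument], dim: int = 50, seed: int = 0) -> EmbeddingTable:
    vocab: set[str] = set()
    for doc in docs:
        for page in doc.pages:
            vocab.update(tokenize(page_text(page)))
    return EmbeddingTable.random(vocab, dim=dim, seed=seed)


def train_page_detector(
    docs: list[SyntheticDocument],
    seed: int = 0,
    class_weight_line: float = 50.0,
    class_weight_page: float = 5.0,
    line_epochs: int = 3,
    hidden: int = 32,
    embeddings: EmbeddingTable | None = None,
) -> PageDetector:
    """Train both levels of the stacked generalizer on a synthetic corpus."""
    embeddings = embeddings or corpus_embeddings(docs, seed=seed)
    data = line_dataset(docs, embeddings)
    line_model, _ = train_line_classifier(
        data, class_weight_pos=class_weight_line, seed=seed, hidden=hidden, epochs=line_epochs
    )
    texts, counts, labels = [], [], []
    for doc in docs:
        for page in doc.pages:
            texts.append(page_text(page))
            counts.append(predict_in_table_lines(line_model, page, embeddings))
            labels.append(int(page.page_index in doc.table_pages))
    page_model = train_page_classifier(
        texts, counts, labels, class_weight_pos=class_weight_page, seed=seed
    )
    return PageDetector(line_model, page_model, embeddings)


def evaluate_page_detector(detector: PageDetector, docs: list[SyntheticDocument]):
    """Page-level precision, recall and F1 over held-out documents."""
    tp = fp = fn = 0
    for doc in docs:
        predicted = set(detector.detect(doc.pages))
        actual = set(doc.table_pages)
        tp += len(predicted & actual)
        fp += len(predicted - actual)
        fn += len(actual - predicted)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "tp": tp, "fp": fp, "fn": fn}
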