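"""Image-modality cell extraction: preprocessing and a pluggable OCR engine.

Cell crops (one per structure-recognition cell box) are converted to
grayscale and contrast-stretched to the full intensity range, then handed to
an engine implementing the single-uniform-block-of-text contract.  The real
engine (Tesseract) is optional and injected; the self-contained
:class:`FakeOCREngine` reads the glyph payload embedded in synthetic crops,
optionally with seeded character-substitution noise, so the image pipeline
can be exercised end to end without an OCR binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import BBox, DetectionRecord, LogicalTable
from .reconstruct import scale_to_page

__all__ = [
    "CellImage",
    "EngineUnavailableError",
    "preprocess_cell_image",
    "FakeOCREngine",
    "TesseractEngine",
    "ocr_cell",
    "reconstruct_table_ocr",
    "synthesize_cell_images",
]


class EngineUnavailableError(RuntimeError):
    """The requested OCR engine is not available in this environment."""


@dataclass
class CellImage:
    """A grayscale (or RGB) pixel grid for one table cell.

    ``text`` is an optional glyph payload carried by synthetic crops; it is
    what the fake engine reads and is ignored by real engines.
    """

    pixels: np.ndarray
    grid_pos: tuple[int, int] | None = None
    source_bbox: BBox | None = None
    text: str | None = None

    def __post_init__(self) -> None:
        if self.pixels.size == 0:
            raise ValueError("empty cell image")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")


def preprocess_cell_image(img: "CellImage | np.ndarray") -> CellImage:
    """Grayscale conversion followed by min-max contrast stretching.

    The stretch maps the darkest pixel to 0 and the brightest to 255;
    constant images are returned unchanged (the stretch is degenerate).
    Idempotent: applying it twice equals applying it once.
    """
    cell = img if isinstance(img, CellImage) else CellImage(np.asarray(img))
    px = np.asarray(cell.pixels, dtype=np.float64)
    if px.ndim == 3:
        px = px.mean(axis=2)
    elif px.ndim != 2:
        raise ValueError("expected a 2-D grayscale or 3-D RGB array")
    lo, hi = px.min(), px.max()
    if hi > lo:
        px = (px - lo) * (255.0 / (hi - lo))
    out = np.round(px).astype(np.uint8)
    return CellImage(out, grid_pos=cell.grid_pos, source_bbox=cell.source_bbox, text=cell.text)


class FakeOCREngine:
    """Lossless synthetic engine reading the payload embedded by the renderer.

    ``error_rate`` injects seeded uniform character substitutions to emulate
    imperfect recognition.
    """

    _ALPHABET = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"

    def __init__(self, error_rate: float = 0.0, seed: int = 0):
        if not 0.0 <= error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        self.error_rate = error_rate
        self._rng = np.random.default_rng(seed)

    def recognize(self, cell: CellImage) -> str:
        if cell.text is None:
            raise EngineUnavailableError(
                "fake engine needs synthetic crops with an embedded glyph payload"
            )
        if self.error_rate == 0.0:
            return cell.text
        chars = list(cell.text)
        for k in range(len(chars)):
            if self._rng.random() < self.error_rate:
                chars[k] = self._ALPHABET[int(self._rng.integers(len(self._ALPHABET)))]
        return "".join(chars)


class TesseractEngine:
    """Adapter for the Tesseract binary in single-block mode (PSM 6)."""

    def __init__(self) -> None:
        try:
            import pytesseract  # noqa: F401

            pytesseract.get_tesseract_version()
        except Exception as exc:  # missing module or binary
            raise EngineUnavailableError(
                "Tesseract OCR is not available; install pytesseract and the "
                "tesseract binary, or inject another engine"
            ) from exc
        self._pt = pytesseract

    def recognize(self, cell: CellImage) -> str:
        return self._pt.image_to_string(cell.pixels, config="--psm 6")


def ocr_cell(img: "CellImage | np.ndarray", engine) -> str:
    """Preprocess one crop and recognize it; trailing whitespace stripped."""
    cell = preprocess_cell_image(img)
    return engine.recognize(cell).rstrip()


def reconstruct_table_ocr(
    detections: list[DetectionRecord],
    cell_images: dict[tuple[int, int], CellImage],
    engine=None,
    page_size: tuple[float, float] = (612.0, 792.0),
) -> LogicalTable:
    """Assemble a grid purely from the image modality.

    The grid shape comes from the detected row and column boxes (rows sorted
    by y across pages in page order, columns by x); every (row, column) cell
    must have a crop in ``cell_images``, whose recognized text fills the grid.
    """
    engine = engine if engine is not None else FakeOCREngine()
    tables = [d for d in detections if d.label == "table"]
    if not tables:
        raise ValueError("no table detection")
    pages = sorted({d.page_index for d in tables})
    rows: list[tuple[int, float]] = []
    n_cols = 0
    for p in pages:
        prow = sorted(
            (scale_to_page(d, *page_size).y_min for d in detections
             if d.label == "table_row" and d.page_index == p)
        )
        rows.extend((p, y) for y in prow)
        n_cols = max(
            n_cols, sum(1 for d in detections if d.label == "table_column" and d.page_index == p)
        )
    if not rows or n_cols == 0:
        raise ValueError("row/column structure detections are required for the image pipeline")
    cells: list[list[str]] = []
    for i in range(len(rows)):
        row = []
        for j in range(n_cols):
            if (i, j) not in cell_images:
                raise ValueError(f"missing crop for detected cell ({i}, {j})")
            row.append(ocr_cell(cell_images[(i, j)], engine))
        cells.append(row)
    return LogicalTable(cells=cells)


def synthesize_cell_images(
    table: LogicalTable, rng_seed: int = 0, glyph_size: int = 4
) -> dict[tuple[int, int], CellImage]:
    """Synthetic cell crops for a logical grid (fixture generator).

    Each crop is a plain bitmap — one dark block per glyph on a light
    background — with the cell's text carried as the embedded payload that
    :class:`FakeOCREngine` reads.  Not a rendering of real fonts.
    """
    rng = np.random.default_rng(rng_seed)
    out: dict[tuple[int, int], CellImage] = {}
    for i, row in enumerate(table.cells):
        for j, text in enumerate(row):
            w = max(8, glyph_size * (len(text) + 1))
            img = np.full((3 * glyph_size, w), 220, dtype=np.uint8)
            img += rng.integers(0, 20, size=img.shape, dtype=np.uint8)
            np.clip(img, 0, 255, out=img)
            for k, ch in enumerate(text):
                if not ch.isspace():
                    x0 = k * glyph_size
                    img[glyph_size : 2 * glyph_size, x0 : x0 + glyph_size - 1] = 30
            out[(i, j)] = CellImage(img, grid_pos=(i, j), text=text)
    return out
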