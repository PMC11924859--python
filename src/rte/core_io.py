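"""Domain types and interchange-format readers/writers.

Every geometric object in the package lives in page points (1/72 inch) with a
top-left origin and y increasing downward — the same convention page images
use, so detector output and PDF-extracted character boxes compose without
sign flips.  Extractors that emit bottom-left-origin PDF coordinates can be
accommodated with ``flip_y=True`` on :func:`read_charboxes`.

Interchange formats
-------------------
* character boxes: JSONL, either one object per page
  (``{"page", "w", "h", "chars": [...], "lines": [...]}``) or one object per
  character (``{"page", "c", "x0", "y0", "x1", "y1"}``);
* detections: a JSON array of labeled, scored boxes in source-image pixels;
* logical tables: JSON (lossless canonical form), RFC-4180 CSV, or HTML.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable

from lxml import etree

__all__ = [
    "BBox",
    "CharBox",
    "GraphicsLine",
    "DetectionRecord",
    "CellSpan",
    "LogicalTable",
    "PageRecord",
    "ValidationError",
    "read_charboxes",
    "write_charboxes",
    "read_detections",
    "write_detections",
    "read_table",
    "write_table",
    "read_jats_tables",
]

DETECTION_LABELS = ("table", "table_column", "table_row", "table_cell", "spanning_cell")

#: default page size (US letter, points) for the per-character JSONL dialect,
#: which carries no page geometry of its own.
DEFAULT_PAGE_SIZE = (612.0, 792.0)


class ValidationError(ValueError):
    """An input record violates a domain-type invariant."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in page points, top-left origin, y down."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite bbox coordinates: {vals}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(f"degenerate bbox: {vals}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def x_center(self) -> float:
        return 0.5 * (self.x_min + self.x_max)

    @property
    def y_center(self) -> float:
        return 0.5 * (self.y_min + self.y_max)

    def iou(self, other: "BBox") -> float:
        ix = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        iy = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if ix <= 0 or iy <= 0:
            return 0.0
        inter = ix * iy
        union = self.width * self.height + other.width * other.height - inter
        return inter / union


@dataclass(frozen=True)
class CharBox:
    """A single glyph anchored to its bounding box on a page."""

    glyph: str
    bbox: BBox
    page_index: int = 0

    def __post_init__(self) -> None:
        if len(self.glyph) != 1:
            raise ValidationError(f"glyph must be one character, got {self.glyph!r}")
        if self.page_index < 0:
            raise ValidationError("page_index must be >= 0")


@dataclass(frozen=True)
class GraphicsLine:
    """A horizontal or vertical rule drawn by PDF graphics operators.

    The span box may be degenerate along the rule's own axis (tolerance
    0.5 pt), so it is not a :class:`BBox`.
    """

    orientation: str  # "horizontal" | "vertical"
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    page_index: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ("horizontal", "vertical"):
            raise ValidationError(f"bad orientation {self.orientation!r}")
        dx, dy = self.x_max - self.x_min, self.y_max - self.y_min
        if dx < -0.5 or dy < -0.5:
            raise ValidationError("inverted graphics line span")
        if self.orientation == "horizontal" and dy > 0.5 and dy > dx:
            raise ValidationError("horizontal line with dominant vertical extent")
        if self.orientation == "vertical" and dx > 0.5 and dx > dy:
            raise ValidationError("vertical line with dominant horizontal extent")


@dataclass(frozen=True)
class DetectionRecord:
    """One labeled, scored box from table detection / structure recognition.

    Coordinates are in source-image pixels; :func:`rte.reconstruct.scale_to_page`
    converts them to page points.
    """

    label: str
    score: float
    bbox: BBox
    page_index: int
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        if self.label not in DETECTION_LABELS:
            raise ValidationError(
                f"unknown detection label {self.label!r}; allowed: {DETECTION_LABELS}"
            )
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score {self.score} outside [0, 1]")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValidationError("image dimensions must be positive")
        if (
            self.bbox.x_min < 0
            or self.bbox.y_min < 0
            or self.bbox.x_max > self.image_width
            or self.bbox.y_max > self.image_height
        ):
            raise ValidationError("detection bbox outside image bounds")


@dataclass(frozen=True)
class CellSpan:
    """Half-open grid rectangle [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end and 0 <= self.col_start < self.col_end):
            raise ValidationError(f"bad span {self}")

    @property
    def n_cells(self) -> int:
        return (self.row_end - self.row_start) * (self.col_end - self.col_start)


@dataclass
class LogicalTable:
    """An R x C grid of cell strings — the target of reconstruction.

    ``cells[i][j]`` holds the content of row i, column j.  Multi-row or
    multi-column cells are recorded in ``spans`` (half-open rectangles that
    must tile without overlap); the grid itself stays rectangular, with the
    spanned content repeated at every covered position.  ``cell_boxes`` is an
    optional parallel grid of physical boxes (used by the location metric).
    """

    cells: list[list[str]]
    n_header_rows: int = 0
    spans: list[CellSpan] = field(default_factory=list)
    cell_boxes: list[list[BBox | None]] | None = None

    def __post_init__(self) -> None:
        if self.n_header_rows < 0:
            raise ValidationError("n_header_rows must be >= 0")
        widths = {len(r) for r in self.cells}
        if len(widths) > 1:
            raise ValidationError(f"ragged table: row widths {sorted(widths)}")
        self._check_spans()

    def _check_spans(self) -> None:
        if not self.spans:
            return
        covered: set[tuple[int, int]] = set()
        for s in self.spans:
            if s.row_end > self.n_rows or s.col_end > self.n_cols:
                raise ValidationError(f"span {s} exceeds grid {self.n_rows}x{self.n_cols}")
            for i in range(s.row_start, s.row_end):
                for j in range(s.col_start, s.col_end):
                    if (i, j) in covered:
                        raise ValidationError(f"overlapping spans at ({i}, {j})")
                    covered.add((i, j))

    @property
    def n_rows(self) -> int:
        return len(self.cells)

    @property
    def n_cols(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def span_at(self, i: int, j: int) -> CellSpan:
        """Span rectangle covering grid position (i, j); 1x1 by default."""
        for s in self.spans:
            if s.row_start <= i < s.row_end and s.col_start <= j < s.col_end:
                return s
        return CellSpan(i, i + 1, j, j + 1)

    def row(self, i: int) -> list[str]:
        return list(self.cells[i])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogicalTable):
            return NotImplemented
        return (
            self.cells == other.cells
            and self.n_header_rows == other.n_header_rows
            and sorted(self.spans, key=lambda s: (s.row_start, s.col_start))
            == sorted(other.spans, key=lambda s: (s.row_start, s.col_start))
        )


@dataclass
class PageRecord:
    """All glyphs and rules of one page, in page points."""

    page_index: int
    page_width: float
    page_height: float
    char_boxes: list[CharBox] = field(default_factory=list)
    graphics: list[GraphicsLine] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cb in self.char_boxes:
            if cb.page_index != self.page_index:
                raise ValidationError(
                    f"char box on page {cb.page_index} inside PageRecord {self.page_index}"
                )
        for gl in self.graphics:
            if gl.page_index != self.page_index:
                raise ValidationError(
                    f"graphics line on page {gl.page_index} inside PageRecord {self.page_index}"
                )

    @property
    def text(self) -> str:
        return "".join(cb.glyph for cb in self.char_boxes)


# ---------------------------------------------------------------------------
# character-box JSONL
# ---------------------------------------------------------------------------


def _char_from_obj(obj: dict, page_index: int, page_h: float, flip_y: bool) -> CharBox:
    y0, y1 = float(obj["y0"]), float(obj["y1"])
    if flip_y:
        y0, y1 = page_h - y1, page_h - y0
    return CharBox(
        glyph=obj["c"],
        bbox=BBox(float(obj["x0"]), y0, float(obj["x1"]), y1),
        page_index=page_index,
    )


def _line_from_obj(obj: dict, page_index: int, page_h: float, flip_y: bool) -> GraphicsLine:
    y0, y1 = float(obj["y0"]), float(obj["y1"])
    if flip_y:
        y0, y1 = page_h - y1, page_h - y0
    orientation = {"h": "horizontal", "v": "vertical"}.get(obj["o"], obj["o"])
    return GraphicsLine(
        orientation=orientation,
        x_min=float(obj["x0"]),
        y_min=min(y0, y1),
        x_max=float(obj["x1"]),
        y_max=max(y0, y1),
        page_index=page_index,
    )


def read_charboxes(path, flip_y: bool = False) -> list[PageRecord]:
    """Read character boxes (JSONL, per-page or per-char dialect) into pages.

    Glyphs are preserved byte-exactly, including superscripts and arbitrary
    Unicode.  ``flip_y`` converts bottom-left-origin PDF coordinates to the
    package's top-left convention.
    """
    pages: dict[int, PageRecord] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                obj = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from None
            try:
                page_index = int(obj["page"])
                if "chars" in obj or "lines" in obj:  # per-page dialect
                    w = float(obj.get("w", DEFAULT_PAGE_SIZE[0]))
                    h = float(obj.get("h", DEFAULT_PAGE_SIZE[1]))
                    page = pages.setdefault(page_index, PageRecord(page_index, w, h))
                    page.page_width, page.page_height = w, h
                    for c in obj.get("chars", ()):
                        page.char_boxes.append(_char_from_obj(c, page_index, h, flip_y))
                    for gl in obj.get("lines", ()):
                        page.graphics.append(_line_from_obj(gl, page_index, h, flip_y))
                else:  # per-char dialect
                    page = pages.setdefault(
                        page_index,
                        PageRecord(page_index, *DEFAULT_PAGE_SIZE),
                    )
                    page.char_boxes.append(
                        _char_from_obj(obj, page_index, page.page_height, flip_y)
                    )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            except (KeyError, TypeError) as exc:
                raise ValueError(f"{path}: line {lineno}: missing field {exc}") from None
    return [pages[k] for k in sorted(pages)]


def write_charboxes(pages: Iterable[PageRecord], path) -> None:
    """Write pages in the per-page JSONL dialect (lossless inverse of reading)."""
    with open(path, "w", encoding="utf-8") as fh:
        for page in pages:
            obj = {
                "page": page.page_index,
                "w": page.page_width,
                "h": page.page_height,
                "chars": [
                    {
                        "c": cb.glyph,
                        "x0": cb.bbox.x_min,
                        "y0": cb.bbox.y_min,
                        "x1": cb.bbox.x_max,
                        "y1": cb.bbox.y_max,
                    }
                    for cb in page.char_boxes
                ],
                "lines": [
                    {
                        "o": gl.orientation[0],
                        "x0": gl.x_min,
                        "y0": gl.y_min,
                        "x1": gl.x_max,
                        "y1": gl.y_max,
                    }
                    for gl in page.graphics
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# detection JSON
# ---------------------------------------------------------------------------


def read_detections(path) -> list[DetectionRecord]:
    """Read a JSON array of detector boxes, in file order."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a JSON array of detection records")
    out = []
    for k, obj in enumerate(data):
        try:
            out.append(
                DetectionRecord(
                    label=obj["label"],
                    score=float(obj["score"]),
                    bbox=BBox(
                        float(obj["x0"]), float(obj["y0"]), float(obj["x1"]), float(obj["y1"])
                    ),
                    page_index=int(obj["page"]),
                    image_width=int(obj["img_w"]),
                    image_height=int(obj["img_h"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {k}: {exc}") from None
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: record {k}: missing field {exc}") from None
    return out


def write_detections(records: Iterable[DetectionRecord], path) -> None:
    data = [
        {
            "label": d.label,
            "score": d.score,
            "page": d.page_index,
            "img_w": d.image_width,
            "img_h": d.image_height,
            "x0": d.bbox.x_min,
            "y0": d.bbox.y_min,
            "x1": d.bbox.x_max,
            "y1": d.bbox.y_max,
        }
        for d in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, ensure_ascii=False, indent=1)


# ---------------------------------------------------------------------------
# logical-table IO (JSON canonical; CSV and HTML for interoperability)
# ---------------------------------------------------------------------------

_FORMATS = ("csv", "json", "html")


def write_table(table: LogicalTable, path, format: str = "json") -> None:
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {_FORMATS}")
    if format == "json":
        obj = {
            "n_header_rows": table.n_header_rows,
            "cells": table.cells,
            "spans": [
                [s.row_start, s.row_end, s.col_start, s.col_end] for s in table.spans
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, ensure_ascii=False, indent=1)
    elif format == "csv":
        # newline="" so embedded \n survives RFC-4180 quoting untouched
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
            for row in table.cells:
                writer.writerow(row)
    else:
        root = etree.Element("table")
        if table.n_header_rows:
            thead = etree.SubElement(root, "thead")
        tbody = etree.SubElement(root, "tbody")
        for i, row in enumerate(table.cells):
            parent = thead if i < table.n_header_rows else tbody
            tr = etree.SubElement(parent, "tr")
            for j, cell in enumerate(row):
                span = table.span_at(i, j)
                if span.row_start != i or span.col_start != j:
                    continue  # covered by an anchor to the upper-left
                td = etree.SubElement(tr, "th" if i < table.n_header_rows else "td")
                if span.row_end - span.row_start > 1:
                    td.set("rowspan", str(span.row_end - span.row_start))
                if span.col_end - span.col_start > 1:
                    td.set("colspan", str(span.col_end - span.col_start))
                td.text = cell
        with open(path, "wb") as fh:
            fh.write(etree.tostring(root, encoding="utf-8"))


def read_table(path, format: str = "json") -> LogicalTable:
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {_FORMATS}")
    if format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return LogicalTable(
            cells=[[str(c) for c in row] for row in obj["cells"]],
            n_header_rows=int(obj.get("n_header_rows", 0)),
            spans=[CellSpan(*s) for s in obj.get("spans", ())],
        )
    if format == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            rows = [list(r) for r in csv.reader(fh)]
        return LogicalTable(cells=rows)
    with open(path, "rb") as fh:
        root = etree.parse(io.BytesIO(fh.read())).getroot()
    table_el = root if root.tag == "table" else root.find(".//table")
    if table_el is None:
        raise ValueError(f"{path}: no <table> element found")
    return _table_from_html_element(table_el)


def _cell_text(el) -> str:
    return "".join(el.itertext())


def _table_from_html_element(table_el, table_id: str = "<table>") -> LogicalTable:
    """Expand an HTML/JATS <table> element into a rectangular grid.

    Spanned content is repeated at every covered grid position and the span
    rectangle is recorded.  Raises if span expansion cannot produce a
    rectangular grid.
    """
    head_rows = table_el.findall(".//thead/tr")
    body_rows = [
        tr for tr in table_el.findall(".//tr") if tr not in set(head_rows)
    ]
    trs = list(head_rows) + list(body_rows)
    if not trs:
        return LogicalTable(cells=[], n_header_rows=0)

    grid: dict[tuple[int, int], str] = {}
    spans: list[CellSpan] = []
    occupied: set[tuple[int, int]] = set()
    n_cols = 0
    for i, tr in enumerate(trs):
        j = 0
        for td in tr.findall("td") + tr.findall("th"):
            while (i, j) in occupied:
                j += 1
            rs = int(td.get("rowspan", 1) or 1)
            cs = int(td.get("colspan", 1) or 1)
            text = _cell_text(td)
            for di in range(rs):
                for dj in range(cs):
                    pos = (i + di, j + dj)
                    if pos in occupied:
                        raise ValidationError(
                            f"{table_id}: overlapping cells at {pos} after span expansion"
                        )
                    occupied.add(pos)
                    grid[pos] = text
            if rs > 1 or cs > 1:
                spans.append(CellSpan(i, i + rs, j, j + cs))
            j += cs
            n_cols = max(n_cols, j)
    n_rows = max(i for i, _ in occupied) + 1 if occupied else 0
    cells = [[grid.get((i, j), "") for j in range(n_cols)] for i in range(n_rows)]
    return LogicalTable(cells=cells, n_header_rows=len(head_rows), spans=spans)


def read_jats_tables(path) -> list[LogicalTable]:
    """Parse all ``<table-wrap>/<table>`` elements of a JATS XML file.

    Header rows come from ``<thead>``; rowspan/colspan attributes become
    recorded spans with content repeated across the covered grid positions.
    """
    parser = etree.XMLParser(recover=False, resolve_entities=False, no_network=True)
    tree = etree.parse(str(path), parser)
    tables = []
    for k, table_el in enumerate(tree.iter()):
        tag = etree.QName(table_el).localname if isinstance(table_el.tag, str) else None
        if tag != "table":
            continue
        wrap = table_el.getparent()
        tid = wrap.get("id") if wrap is not None and wrap.get("id") else f"table[{k}]"
        tables.append(_table_from_html_element(table_el, table_id=tid))
    return tables
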