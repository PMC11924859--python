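"""Geometric table reconstruction from character boxes and detector output.

The detector works on page images; its boxes are first scaled back to page
points.  Column extents are estimated from the detected cell boxes (they are
far more reliable than row boxes, because columns are separated by wider
gutters than rows).  Character boxes are grouped into text lines by their top
y coordinate and horizontal adjacency; line segments are then binned into the
column ranges, producing one physical grid row per text-line band
(column-only mode) or per detected row rectangle (row mode).  A final
canonicalization pass merges spurious physical rows — superscript/subscript
lines and continuation lines — by two overlap heuristics.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

import numpy as np

from .core_io import BBox, CharBox, DetectionRecord, LogicalTable, PageRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnRanges",
    "TextLine",
    "RowGeometry",
    "scale_to_page",
    "group_cells_into_tsr_rows",
    "estimate_column_count",
    "estimate_column_ranges",
    "build_text_lines",
    "assemble_grid",
    "heuristic_row_merge",
    "reconstruct_table",
]


@dataclass
class ColumnRanges:
    """Ordered, disjoint x-intervals (points) delimiting table columns."""

    intervals: list[tuple[float, float]]
    pad: float = 1.0
    avg_char_width: float = 6.0

    def __post_init__(self) -> None:
        for lo, hi in self.intervals:
            if not lo < hi:
                raise ValueError(f"empty column interval ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(self.intervals, self.intervals[1:]):
            if hi > lo2:
                raise ValueError("column intervals overlap")

    @property
    def n_cols(self) -> int:
        return len(self.intervals)

    def assign(self, x_center: float) -> int:
        """Column index containing x_center, else the nearest interval."""
        for j, (lo, hi) in enumerate(self.intervals):
            if lo <= x_center <= hi:
                return j
        dists = [
            0.0 if lo <= x_center <= hi else min(abs(x_center - lo), abs(x_center - hi))
            for lo, hi in self.intervals
        ]
        j = int(np.argmin(dists))
        logger.debug("segment center %.1f outside all column ranges; using nearest %d", x_center, j)
        return j


@dataclass
class TextLine:
    """A horizontally connected run of glyphs sharing a top-y band."""

    chars: list[CharBox]
    band_index: int
    page_index: int

    def __post_init__(self) -> None:
        self.chars = sorted(self.chars, key=lambda c: c.bbox.x_min)

    @property
    def text(self) -> str:
        return "".join(c.glyph for c in self.chars)

    @property
    def x_min(self) -> float:
        return self.chars[0].bbox.x_min

    @property
    def x_max(self) -> float:
        return max(c.bbox.x_max for c in self.chars)

    @property
    def y_top(self) -> float:
        return min(c.bbox.y_min for c in self.chars)

    @property
    def y_min(self) -> float:
        return self.y_top

    @property
    def y_max(self) -> float:
        return max(c.bbox.y_max for c in self.chars)


@dataclass
class RowGeometry:
    """Physical-row geometry retained for the canonicalization rules."""

    y_min: float
    y_max: float
    x_min: float
    x_max: float
    cell_boxes: list[BBox | None]

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


def scale_to_page(d: DetectionRecord, page_width: float, page_height: float) -> BBox:
    """Scale an image-pixel detection box to page points (per-axis)."""
    if d.image_width <= 0 or d.image_height <= 0:
        raise ValueError("image dimensions must be positive")
    sx = page_width / d.image_width
    sy = page_height / d.image_height
    return BBox(d.bbox.x_min * sx, d.bbox.y_min * sy, d.bbox.x_max * sx, d.bbox.y_max * sy)


# ---------------------------------------------------------------------------
# column/row range estimation
# ---------------------------------------------------------------------------


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def group_cells_into_tsr_rows(
    cell_boxes: list[BBox], row_boxes: list[BBox] | None = None
) -> list[list[BBox]]:
    """Group detected cell boxes into structure-recognition rows.

    Uses the detected row rectangles (maximal vertical overlap) when present,
    otherwise clusters cell y-centers at gaps wider than half the median cell
    height.
    """
    if not cell_boxes:
        return []
    if row_boxes:
        rows: list[list[BBox]] = [[] for _ in row_boxes]
        order = sorted(range(len(row_boxes)), key=lambda k: row_boxes[k].y_min)
        for cb in cell_boxes:
            ovs = [_overlap(cb.y_min, cb.y_max, rb.y_min, rb.y_max) for rb in row_boxes]
            rows[int(np.argmax(ovs))].append(cb)
        return [rows[k] for k in order if rows[k]]
    med_h = statistics.median(b.height for b in cell_boxes)
    by_y = sorted(cell_boxes, key=lambda b: b.y_center)
    grouped: list[list[BBox]] = [[by_y[0]]]
    for b in by_y[1:]:
        if b.y_center - grouped[-1][-1].y_center > 0.5 * med_h:
            grouped.append([b])
        else:
            grouped[-1].append(b)
    return grouped


def estimate_column_count(tsr_rows: list[list[BBox]]) -> int:
    """Column count = lower median of per-row cell counts."""
    if not tsr_rows:
        raise ValueError("no structure-recognition rows")
    counts = sorted(len(r) for r in tsr_rows)
    return counts[(len(counts) - 1) // 2]


def cluster_cells_by_column(cell_boxes: list[BBox], n_cols: int) -> list[list[BBox]]:
    """Split cell boxes into ``n_cols`` groups at the widest x-center gaps."""
    if n_cols < 1:
        raise ValueError("need at least one column")
    boxes = sorted(cell_boxes, key=lambda b: b.x_center)
    if n_cols == 1 or len(boxes) <= n_cols:
        if len(boxes) <= n_cols:
            return [[b] for b in boxes] + [[] for _ in range(n_cols - len(boxes))]
    gaps = [
        (boxes[k + 1].x_center - boxes[k].x_center, k) for k in range(len(boxes) - 1)
    ]
    cuts = sorted(k for _, k in sorted(gaps, key=lambda g: (-g[0], g[1]))[: n_cols - 1])
    groups: list[list[BBox]] = []
    start = 0
    for cut in cuts:
        groups.append(boxes[start : cut + 1])
        start = cut + 1
    groups.append(boxes[start:])
    return groups


def estimate_column_ranges(
    cells_by_column: list[list[BBox]],
    avg_char_width: float,
    pad: float = 1.0,
) -> ColumnRanges:
    """Column x-ranges: [min x_min - pad, max x_max + pad] over its cells.

    The last column is additionally widened by two average character widths
    (tight detector boxes occasionally clip final characters).  Overlapping
    estimates are resolved at the interval midpoints so the result partitions
    the x axis.
    """
    if not cells_by_column or all(not g for g in cells_by_column):
        raise ValueError("no cells to estimate column ranges from")
    intervals: list[tuple[float, float]] = []
    for j, group in enumerate(g for g in cells_by_column if g):
        lo = min(b.x_min for b in group) - pad
        hi = max(b.x_max for b in group) + pad
        intervals.append((lo, hi))
    intervals.sort()
    lo, hi = intervals[-1]
    intervals[-1] = (lo, hi + 2.0 * avg_char_width)
    resolved = [list(iv) for iv in intervals]
    for k in range(len(resolved) - 1):
        if resolved[k][1] > resolved[k + 1][0]:
            mid = 0.5 * (resolved[k][1] + resolved[k + 1][0])
            resolved[k][1] = mid
            resolved[k + 1][0] = mid
    return ColumnRanges(
        intervals=[(lo, hi) for lo, hi in resolved], pad=pad, avg_char_width=avg_char_width
    )


# ---------------------------------------------------------------------------
# text lines
# ---------------------------------------------------------------------------


def average_char_width(chars: list[CharBox]) -> float:
    if not chars:
        return 6.0
    return float(np.mean([c.bbox.width for c in chars]))


def build_text_lines(
    page: PageRecord,
    y_tolerance: float | None = None,
    gap_factor: float = 1.5,
    chars: list[CharBox] | None = None,
) -> list[TextLine]:
    """Group glyphs into text lines by top-y bands and horizontal adjacency.

    Glyphs whose top-y values differ by at most ``y_tolerance`` (default a
    quarter of the estimated line height) share a band; within a band, glyphs
    separated by more than ``gap_factor`` average character widths start a new
    segment.  Superscripts and subscripts have different top-y values than
    their baseline and therefore form separate (spurious) lines, later
    handled by canonicalization.
    """
    glyphs = list(chars) if chars is not None else list(page.char_boxes)
    if not glyphs:
        return []
    med_h = statistics.median(c.bbox.height for c in glyphs)
    if y_tolerance is None:
        y_tolerance = 0.25 * med_h / 0.72  # glyph boxes cover ~72% of the line pitch
    acw = average_char_width(glyphs)

    glyphs.sort(key=lambda c: (c.bbox.y_min, c.bbox.x_min))
    bands: list[list[CharBox]] = [[glyphs[0]]]
    band_start = glyphs[0].bbox.y_min
    for g in glyphs[1:]:
        if g.bbox.y_min - band_start > y_tolerance:
            bands.append([g])
            band_start = g.bbox.y_min
        else:
            bands[-1].append(g)

    lines: list[TextLine] = []
    for b_idx, band in enumerate(bands):
        band.sort(key=lambda c: c.bbox.x_min)
        seg = [band[0]]
        for g in band[1:]:
            if g.bbox.x_min - seg[-1].bbox.x_max > gap_factor * acw:
                lines.append(TextLine(seg, b_idx, page.page_index))
                seg = [g]
            else:
                seg.append(g)
        lines.append(TextLine(seg, b_idx, page.page_index))
    lines.sort(key=lambda l: (l.y_top, l.x_min))
    return lines


# ---------------------------------------------------------------------------
# grid assembly
# ---------------------------------------------------------------------------


def _segments_to_cells(
    segments: list[TextLine], col_ranges: ColumnRanges
) -> tuple[list[str], list[BBox | None]]:
    by_col: list[list[TextLine]] = [[] for _ in range(col_ranges.n_cols)]
    for seg in segments:
        by_col[col_ranges.assign(0.5 * (seg.x_min + seg.x_max))].append(seg)
    cells, boxes = [], []
    for group in by_col:
        group.sort(key=lambda s: (s.y_top, s.x_min))
        cells.append(" ".join(s.text for s in group).strip())
        if group:
            boxes.append(
                BBox(
                    min(s.x_min for s in group),
                    min(s.y_min for s in group),
                    max(s.x_max for s in group),
                    max(s.y_max for s in group),
                )
            )
        else:
            boxes.append(None)
    return cells, boxes


def assemble_grid(
    lines: list[TextLine],
    col_ranges: ColumnRanges,
    row_ranges: list[tuple[float, float]] | None = None,
) -> tuple[LogicalTable, list[RowGeometry]]:
    """Bin line segments into a raw grid.

    Column-only mode (``row_ranges is None``): one physical row per text-line
    band.  Row mode: segments are binned into the given row y-ranges by
    maximal vertical overlap.  Cell text is the left-to-right concatenation
    of the cell's segments with single spaces between segments.
    """
    if not lines:
        return LogicalTable(cells=[]), []
    if row_ranges is None:
        keys = sorted({l.band_index for l in lines}, key=lambda b: min(
            l.y_top for l in lines if l.band_index == b
        ))
        buckets = {k: [l for l in lines if l.band_index == k] for k in keys}
    else:
        order = sorted(range(len(row_ranges)), key=lambda k: row_ranges[k][0])
        buckets = {k: [] for k in order}
        for l in lines:
            ovs = [_overlap(l.y_min, l.y_max, r0, r1) for r0, r1 in row_ranges]
            buckets[int(np.argmax(ovs))].append(l)
        keys = [k for k in order if buckets[k]]

    rows, geom = [], []
    for k in keys:
        segs = buckets[k]
        cells, boxes = _segments_to_cells(segs, col_ranges)
        rows.append(cells)
        geom.append(
            RowGeometry(
                y_min=min(s.y_min for s in segs),
                y_max=max(s.y_max for s in segs),
                x_min=min(s.x_min for s in segs),
                x_max=max(s.x_max for s in segs),
                cell_boxes=boxes,
            )
        )
    table = LogicalTable(cells=rows)
    table.cell_boxes = [g.cell_boxes for g in geom]
    return table, geom


# ---------------------------------------------------------------------------
# heuristic row merge (canonicalization)
# ---------------------------------------------------------------------------


def _merge_cells(upper: list[str], lower: list[str], ug: RowGeometry, lg: RowGeometry) -> list[str]:
    out = []
    for j, (a, b) in enumerate(zip(upper, lower)):
        if not a:
            out.append(b)
        elif not b:
            out.append(a)
        else:
            # order by horizontal position, so raised trailing superscripts land after
            ua, ub = ug.cell_boxes[j], lg.cell_boxes[j]
            if ua is not None and ub is not None and ub.x_min < ua.x_min:
                a, b = b, a
            out.append(f"{a} {b}")
    return out


def _merge_geom(a: RowGeometry, b: RowGeometry) -> RowGeometry:
    boxes: list[BBox | None] = []
    for ba, bb in zip(a.cell_boxes, b.cell_boxes):
        if ba is None:
            boxes.append(bb)
        elif bb is None:
            boxes.append(ba)
        else:
            boxes.append(
                BBox(
                    min(ba.x_min, bb.x_min),
                    min(ba.y_min, bb.y_min),
                    max(ba.x_max, bb.x_max),
                    max(ba.y_max, bb.y_max),
                )
            )
    return RowGeometry(
        y_min=min(a.y_min, b.y_min),
        y_max=max(a.y_max, b.y_max),
        x_min=min(a.x_min, b.x_min),
        x_max=max(a.x_max, b.x_max),
        cell_boxes=boxes,
    )


def heuristic_row_merge(
    raw: LogicalTable,
    geometry: list[RowGeometry],
    tsr_row_boxes: list[BBox],
    rect_overlap: float = 0.70,
    text_overlap: float = 0.50,
) -> LogicalTable:
    """Merge spurious physical rows by the two canonicalization rules.

    Rule 1: a physical row whose vertical interval overlaps its nearest
    detected row rectangle by at least 70% (of the row's own height) is
    merged into the physical row anchored by that rectangle — this absorbs
    superscript/subscript lines.  Rule 2: a row with at least one empty cell,
    below a closest row without empty cells, whose vertical text band
    overlaps that row's band by at least 50% (of the smaller band), is merged
    upward.  Rules are applied top-down until neither fires.  Merged cells
    are joined with a single space; empty cells absorb content unchanged.
    """
    rows = [list(r) for r in raw.cells]
    geom = list(geometry)

    def nearest_rect(g: RowGeometry) -> int | None:
        if not tsr_row_boxes:
            return None
        ovs = [_overlap(g.y_min, g.y_max, rb.y_min, rb.y_max) for rb in tsr_row_boxes]
        if max(ovs) > 0:
            return int(np.argmax(ovs))
        centers = [abs(0.5 * (g.y_min + g.y_max) - rb.y_center) for rb in tsr_row_boxes]
        return int(np.argmin(centers))

    def anchor_of(rect_idx: int) -> int:
        rb = tsr_row_boxes[rect_idx]
        ovs = [_overlap(g.y_min, g.y_max, rb.y_min, rb.y_max) for g in geom]
        return int(np.argmax(ovs))

    changed = True
    guard = 0
    while changed and guard < 10 * (len(rows) + 1):
        changed = False
        guard += 1
        for r in range(len(rows)):
            g = geom[r]
            # Rule 1 — row rectangle absorption
            rect = nearest_rect(g)
            if rect is not None and g.height > 0:
                ov = _overlap(g.y_min, g.y_max, tsr_row_boxes[rect].y_min, tsr_row_boxes[rect].y_max)
                if ov / g.height >= rect_overlap:
                    a = anchor_of(rect)
                    if a != r:
                        lo, hi = min(a, r), max(a, r)
                        logger.debug("rule1: merging row %d into %d", r, a)
                        rows[lo] = _merge_cells(rows[lo], rows[hi], geom[lo], geom[hi])
                        geom[lo] = _merge_geom(geom[lo], geom[hi])
                        del rows[hi], geom[hi]
                        changed = True
                        break
            # Rule 2 — continuation absorption
            if r > 0 and any(not c for c in rows[r]) and all(rows[r - 1]):
                above = geom[r - 1]
                denom = min(g.height, above.height)
                if denom > 0:
                    ov = _overlap(g.y_min, g.y_max, above.y_min, above.y_max)
                    if ov / denom >= text_overlap:
                        logger.debug("rule2: merging row %d upward", r)
                        rows[r - 1] = _merge_cells(rows[r - 1], rows[r], geom[r - 1], geom[r])
                        geom[r - 1] = _merge_geom(geom[r - 1], geom[r])
                        del rows[r], geom[r]
                        changed = True
                        break
    out = LogicalTable(cells=rows)
    out.cell_boxes = [g.cell_boxes for g in geom]
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def reconstruct_table(
    detections: list[DetectionRecord],
    pages: list[PageRecord],
    mode: str = "col",
    pad: float = 1.0,
    y_tolerance: float | None = None,
    gap_factor: float = 1.5,
) -> LogicalTable:
    """Full geometric reconstruction on the pages carrying a table detection.

    Scales detections to page coordinates, estimates column (and, in row
    mode, row) ranges, builds text lines clipped to the table box, assembles
    the grid, and (column mode) applies the heuristic row merge.  Rows of
    multi-page tables are concatenated in page order.
    """
    if mode not in ("col", "row"):
        raise ValueError(f"mode must be 'col' or 'row', got {mode!r}")
    page_map = {p.page_index: p for p in pages}
    table_pages = sorted(
        {d.page_index for d in detections if d.label == "table" and d.page_index in page_map}
    )
    if not table_pages:
        raise ValueError("no table detection on the given pages")

    all_rows: list[list[str]] = []
    all_boxes: list[list[BBox | None]] = []
    n_cols_seen = 0
    for p in table_pages:
        page = page_map[p]
        dets = [d for d in detections if d.page_index == p]
        scale = lambda d: scale_to_page(d, page.page_width, page.page_height)
        table_box = max(
            (d for d in dets if d.label == "table"), key=lambda d: d.score
        )
        tb = scale(table_box)
        cell_boxes = [scale(d) for d in dets if d.label in ("table_cell", "spanning_cell")]
        row_boxes = sorted((scale(d) for d in dets if d.label == "table_row"), key=lambda b: b.y_min)
        col_boxes = [scale(d) for d in dets if d.label == "table_column"]

        glyphs = [
            cb
            for cb in page.char_boxes
            if tb.x_min <= cb.bbox.x_center <= tb.x_max
            and tb.y_min <= cb.bbox.y_center <= tb.y_max
        ]
        if not glyphs:
            continue
        acw = average_char_width(glyphs)

        if cell_boxes:
            tsr_rows = group_cells_into_tsr_rows(cell_boxes, row_boxes or None)
            n_cols = estimate_column_count(tsr_rows)
            by_col = cluster_cells_by_column(cell_boxes, n_cols)
            col_ranges = estimate_column_ranges(by_col, acw, pad=pad)
        elif col_boxes:
            by_col = [[b] for b in sorted(col_boxes, key=lambda b: b.x_min)]
            col_ranges = estimate_column_ranges(by_col, acw, pad=pad)
        else:
            raise ValueError(f"page {p}: no cell or column detections inside the table")

        lines = build_text_lines(page, y_tolerance=y_tolerance, gap_factor=gap_factor, chars=glyphs)
        if mode == "row":
            if not row_boxes:
                raise ValueError(f"page {p}: row mode requires table_row detections")
            ranges = [(b.y_min, b.y_max) for b in row_boxes]
            grid, geom = assemble_grid(lines, col_ranges, ranges)
        else:
            grid, geom = assemble_grid(lines, col_ranges, None)
            grid = heuristic_row_merge(grid, geom, row_boxes)

        n_cols_seen = max(n_cols_seen, grid.n_cols)
        all_rows.extend(grid.cells)
        all_boxes.extend(grid.cell_boxes or [[None] * grid.n_cols for _ in grid.cells])

    # pad pages that estimated fewer columns so the stitched grid is rectangular
    for r, (row, boxes) in enumerate(zip(all_rows, all_boxes)):
        if len(row) < n_cols_seen:
            all_rows[r] = row + [""] * (n_cols_seen - len(row))
            all_boxes[r] = boxes + [None] * (n_cols_seen - len(boxes))
    out = LogicalTable(cells=all_rows)
    out.cell_boxes = all_boxes
    return out
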