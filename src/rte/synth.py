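"""Synthetic key-resource tables, their rendering, and simulated cell overflow.

Three jobs live here:

1. :func:`generate_resource_table` builds STAR*Methods-style three-column
   tables (resource name / source / identifier) with RRID-like identifiers,
   catalog numbers, bracketed organism nomenclature and optional superscript
   markers.
2. :func:`simulate_overflow` implements the simulated cell-overflow training
   scheme: tables with at least one row longer than 90 characters are
   allotted a total row width (80 characters for narrow tables, 90
   otherwise), that width is divided among columns in proportion to each
   column's mean length plus standard deviation, over-wide cells are
   word-wrapped into fragments, and consecutive fragment pairs become
   positive merge-classifier instances while vertically neighboring
   non-overflowing cells supply negatives.
3. :func:`render_table` lays the (possibly over-segmented) grid out as
   monospace character boxes with matching table / column / row / cell
   detection boxes, emulating what a PDF extractor plus an image-space table
   detector would produce — optionally with Gaussian jitter on the detection
   boxes and page breaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (
    BBox,
    CharBox,
    DetectionRecord,
    GraphicsLine,
    LogicalTable,
    PageRecord,
)

__all__ = [
    "LayoutSpec",
    "OverflowConfig",
    "MergeInstance",
    "generate_resource_table",
    "select_for_overflow",
    "allocate_column_widths",
    "split_cell",
    "join_fragments",
    "simulate_overflow",
    "merge_row_groups",
    "render_table",
    "generate_document",
    "OracleMergeScorer",
    "SUPERSCRIPT_CHARS",
    "HEADER",
]

#: glyphs the renderer raises above the baseline (superscript footnote marks)
SUPERSCRIPT_CHARS = frozenset("†‡§")

HEADER = ["REAGENT or RESOURCE", "SOURCE", "IDENTIFIER"]


@dataclass(frozen=True)
class LayoutSpec:
    """Monospace layout geometry, all lengths in page points."""

    char_width: float = 5.0
    line_height: float = 12.0
    column_gap: float = 15.0
    page_width: float = 612.0
    page_height: float = 792.0
    max_lines_per_page: int = 55
    jitter_sd: float = 0.0
    margin: float = 36.0

    def __post_init__(self) -> None:
        if min(self.char_width, self.line_height, self.column_gap, self.page_width,
               self.page_height, self.max_lines_per_page) <= 0:
            raise ValueError("layout dimensions must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class OverflowConfig:
    """Thresholds of the simulated-overflow scheme (character counts).

    A table qualifies when some row's total content length exceeds
    ``selection_threshold``; the allotted total row width W is
    ``narrow_width`` when the longest row is shorter than
    ``narrow_table_cutoff`` and ``selection_threshold`` otherwise.
    """

    selection_threshold: int = 90
    narrow_table_cutoff: int = 100
    narrow_width: int = 80
    seed: int = 0
    negative_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.narrow_width < self.selection_threshold < self.narrow_table_cutoff:
            raise ValueError("need narrow_width < selection_threshold < narrow_table_cutoff")


@dataclass(frozen=True)
class MergeInstance:
    """One (upper cell, lower cell, merge/no-merge) training triple."""

    upper: str
    lower: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.label == 1 and (not self.upper or not self.lower):
            raise ValueError("positive instances need non-empty fragments")


# ---------------------------------------------------------------------------
# table generator
# ---------------------------------------------------------------------------

_HOSTS = ["Mouse", "Rabbit", "Goat", "Rat", "Chicken", "Human"]
_CLONALITY = ["monoclonal", "polyclonal"]
_TARGETS = [
    "GFAP", "NeuN", "Iba1", "CD31", "vimentin", "nestin", "beta-actin",
    "tubulin", "MAP2", "synapsin", "PSD95", "tau", "parvalbumin", "calbindin",
]
_CONJUGATES = ["Alexa Fluor 488", "Alexa Fluor 594", "Cy3", "HRP", "biotin"]
# vendor words kept short so they fit even narrow simulated column widths
_VENDORS = [
    "Abcam", "Sigma", "Thermo", "CST", "Merck", "Roche", "Promega", "Biorad",
    "NEB", "Dako",
]
_ORGANISM_STRAINS = [
    "w[1118]", "y[1] w[*]", "C57BL/6J", "BALB/cByJ", "Thy1-YFP 16Jrs",
    "vglut2a:GFP", "elavl3:GCaMP6s",
]
_ORGANISM_KINDS = ["Drosophila", "Mouse", "Zebrafish", "Rat"]
_SOFTWARE = ["ImageJ", "FIJI", "Prism", "MATLAB", "CellProfiler", "Python"]
_CHEMICALS = ["DAPI", "PFA", "Triton X-100", "tamoxifen", "DMSO"]


def _vendor(rng: np.random.Generator) -> str:
    # a country suffix keeps source cells from collapsing to tiny simulated widths
    return f"{rng.choice(_VENDORS)} ({rng.choice(['USA', 'UK', 'Germany', 'Japan'])})"


def _rrid(rng: np.random.Generator, prefix: str = "AB") -> str:
    return f"RRID:{prefix}_{rng.integers(10000, 99999)}"


def _catalog(rng: np.random.Generator) -> str:
    return f"Cat# {rng.choice(['ab', 'MAB', 'A', 'sc-'])}{rng.integers(100, 99999)}"


def _antibody_row(rng: np.random.Generator, long: bool) -> list[str]:
    host = rng.choice(_HOSTS)
    clon = rng.choice(_CLONALITY)
    target = rng.choice(_TARGETS)
    name = f"{host} {clon} anti-{target} antibody"
    ident = f"{_catalog(rng)}; {_rrid(rng, 'AB')}"
    if long:
        name += f" clone {rng.choice(list('ABCDEFG'))}{rng.integers(1, 99)}"
        name += f" conjugated to {rng.choice(_CONJUGATES)}"
        ident += f"; Lot {rng.integers(1000, 99999)}"
    return [name, _vendor(rng), ident]


def _organism_row(rng: np.random.Generator, long: bool) -> list[str]:
    kind = rng.choice(_ORGANISM_KINDS)
    strain = rng.choice(_ORGANISM_STRAINS)
    name = f"{kind}: {strain}"
    if long:
        name += f" crossed to {rng.choice(_ORGANISM_STRAINS)} background line {rng.integers(1, 60)}"
    source = f"{rng.choice(['BDSC', 'JAX', 'ZIRC', 'Charles River'])} stock"
    ident = f"{_rrid(rng, rng.choice(['BDSC', 'MGI', 'ZFIN']))}; stock {rng.integers(100, 9999)}"
    return [name, source, ident]


def _software_row(rng: np.random.Generator, long: bool) -> list[str]:
    name = f"{rng.choice(_SOFTWARE)} v{rng.integers(1, 10)}.{rng.integers(0, 10)}"
    if long:
        name += " with custom analysis scripts for batch segmentation and counting"
    ident = f"{_rrid(rng, 'SCR')}; release {rng.integers(2015, 2025)}"
    return [name, "open source tool", ident]


def _chemical_row(rng: np.random.Generator, long: bool) -> list[str]:
    name = str(rng.choice(_CHEMICALS))
    if long:
        name += f" reconstituted in {rng.choice(['PBS', 'DMSO', 'water'])} at {rng.integers(1, 50)} mg/ml stock"
    ident = f"{_catalog(rng)}; CAS {rng.integers(50, 99999)}-{rng.integers(10, 99)}-{rng.integers(0, 9)}"
    return [name, _vendor(rng), ident]


_ROW_MAKERS = [_antibody_row, _organism_row, _software_row, _chemical_row]


def generate_resource_table(
    n_rows: int,
    rng_seed: int,
    overflow: bool = True,
    long_row_prob: float = 0.4,
    superscript_prob: float = 0.0,
) -> LogicalTable:
    """Generate a seeded three-column key-resource table with one header row.

    ``overflow=True`` guarantees at least one row whose total content length
    exceeds 90 characters (the overflow-selection threshold), so the table
    qualifies for :func:`simulate_overflow`; ``overflow=False`` caps every
    row below that threshold.  ``superscript_prob`` appends a superscript
    footnote marker to some resource names (rendered raised).
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(rng_seed)
    rows: list[list[str]] = []
    long_flags = rng.random(n_rows) < (long_row_prob if overflow else 0.0)
    if overflow and not long_flags.any():
        long_flags[rng.integers(0, n_rows)] = True
    for i in range(n_rows):
        maker = _ROW_MAKERS[int(rng.integers(0, len(_ROW_MAKERS)))]
        row = maker(rng, bool(long_flags[i]))
        if superscript_prob > 0 and rng.random() < superscript_prob:
            row[0] += rng.choice(sorted(SUPERSCRIPT_CHARS))
        rows.append(row)
    if overflow:
        # guarantee the selection criterion even if the long template came out short
        widths = [sum(len(c) for c in r) for r in rows]
        k = int(np.argmax(widths))
        while sum(len(c) for c in rows[k]) <= 90:
            rows[k][0] += " affinity purified"
    return LogicalTable(cells=[list(HEADER)] + rows, n_header_rows=1)


# ---------------------------------------------------------------------------
# simulated overflow
# ---------------------------------------------------------------------------


def select_for_overflow(
    table: LogicalTable, cfg: OverflowConfig = OverflowConfig()
) -> tuple[bool, int]:
    """Overflow-selection rule and total-width allotment.

    A table is selected when some row's total character count (sum of its
    cell lengths) exceeds the selection threshold (90).  The allotted total
    row width W is 80 characters when the longest row totals under 100
    characters, else 90.
    """
    totals = [sum(len(c) for c in row) for row in table.cells]
    if not totals:
        return False, cfg.narrow_width
    longest = max(totals)
    selected = longest > cfg.selection_threshold
    w = cfg.narrow_width if longest < cfg.narrow_table_cutoff else cfg.selection_threshold
    return selected, w


def allocate_column_widths(table: LogicalTable, total_width: int) -> list[int]:
    """Divide W among columns in proportion to mean + sd of column lengths.

    Rounded by largest remainder so the result sums exactly to W; every
    column keeps at least one character.
    """
    n_cols = table.n_cols
    if total_width < n_cols:
        raise ValueError(f"total width {total_width} < {n_cols} columns")
    lengths = np.array([[len(c) for c in row] for row in table.cells], dtype=float)
    weights = lengths.mean(axis=0) + lengths.std(axis=0)
    if weights.sum() <= 0:
        weights = np.ones(n_cols)
    raw = total_width * weights / weights.sum()
    base = np.floor(raw).astype(int)
    remainder = raw - base
    # largest remainder; ties broken toward the leftmost column
    order = sorted(range(n_cols), key=lambda j: (-remainder[j], j))
    for j in order[: total_width - int(base.sum())]:
        base[j] += 1
    widths = base.tolist()
    for j in range(n_cols):  # enforce the >= 1 floor by taking from the widest
        while widths[j] < 1:
            widths[int(np.argmax(widths))] -= 1
            widths[j] += 1
    return widths


def split_cell(content: str, width: int) -> list[str]:
    """Greedy word wrap of ``content`` into fragments of at most ``width``.

    Splits at spaces when possible; a word longer than the width is split at
    the width boundary.  Joining space-split fragments with single spaces
    (and hard-split fragments directly) reproduces the content exactly.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    fragments: list[str] = []
    cur: str | None = None
    for word in content.split(" "):
        pieces = [word[k : k + width] for k in range(0, len(word), width)] or [""]
        for idx, piece in enumerate(pieces):
            if idx > 0:  # continuation of a hard-split word
                fragments.append(cur)  # type: ignore[arg-type]
                cur = piece
            elif cur is None:
                cur = piece
            elif len(cur) + 1 + len(piece) <= width:
                cur = f"{cur} {piece}"
            else:
                fragments.append(cur)
                cur = piece
    fragments.append(cur if cur is not None else "")
    return fragments


def join_fragments(fragments: list[str]) -> str:
    """Single-space join — the lossless inverse of space-splitting."""
    return " ".join(fragments)


def simulate_overflow(
    table: LogicalTable, cfg: OverflowConfig = OverflowConfig()
) -> tuple[LogicalTable, list[list[int]], list[MergeInstance]]:
    """Over-segment a table by wrapping over-wide cells into extra rows.

    Returns the over-segmented grid, ``gold_row_groups`` (the physical row
    indices of each logical row), and labeled merge instances: positives are
    consecutive fragment pairs within a split cell, negatives are vertically
    neighboring same-column cell pairs of distinct logical rows where both
    cells fit their column (sampled 1:1 with positives by default, seeded
    from the config).
    """
    _, total_width = select_for_overflow(table, cfg)
    widths = allocate_column_widths(table, total_width)
    rng = np.random.default_rng(cfg.seed)

    phys_rows: list[list[str]] = []
    groups: list[list[int]] = []
    positives: list[MergeInstance] = []
    overflowed: list[list[bool]] = []
    for row in table.cells:
        frags = [
            split_cell(cell, widths[j]) if len(cell) > widths[j] else [cell]
            for j, cell in enumerate(row)
        ]
        overflowed.append([len(f) > 1 for f in frags])
        for f in frags:
            for a, b in zip(f, f[1:]):
                positives.append(MergeInstance(a, b, 1))
        depth = max(len(f) for f in frags)
        start = len(phys_rows)
        for k in range(depth):
            phys_rows.append([f[k] if k < len(f) else "" for f in frags])
        groups.append(list(range(start, start + depth)))

    neg_candidates = [
        (table.cells[i][j], table.cells[i + 1][j])
        for i in range(table.n_rows - 1)
        for j in range(table.n_cols)
        if not overflowed[i][j] and not overflowed[i + 1][j]
    ]
    n_neg = min(len(neg_candidates), int(round(cfg.negative_ratio * len(positives))))
    idx = rng.choice(len(neg_candidates), size=n_neg, replace=False) if neg_candidates else []
    negatives = [MergeInstance(neg_candidates[k][0], neg_candidates[k][1], 0) for k in idx]

    overseg = LogicalTable(cells=phys_rows, n_header_rows=table.n_header_rows)
    return overseg, groups, positives + negatives


def merge_row_groups(overseg: LogicalTable, groups: list[list[int]]) -> LogicalTable:
    """Undo over-segmentation given the gold row grouping (space-joining)."""
    cells = []
    for group in groups:
        cells.append(
            [
                join_fragments([overseg.cells[k][j] for k in group if overseg.cells[k][j]])
                for j in range(overseg.n_cols)
            ]
        )
    return LogicalTable(cells=cells, n_header_rows=overseg.n_header_rows)


class OracleMergeScorer:
    """Synthetic oracle merge classifier for tests.

    Scores 1.0 exactly when the lower string is the fragment that follows the
    tail of the upper string inside some split cell of the fixture it was
    built from, else 0.0.  Stands in for a trained classifier when the test
    needs perfect merge decisions.
    """

    def __init__(self, table: LogicalTable, cfg: OverflowConfig = OverflowConfig()):
        _, total_width = select_for_overflow(table, cfg)
        widths = allocate_column_widths(table, total_width)
        self._pairs: set[tuple[str, str]] = set()
        for row in table.cells:
            for j, cell in enumerate(row):
                if len(cell) > widths[j]:
                    frags = split_cell(cell, widths[j])
                    for a, b in zip(frags, frags[1:]):
                        self._pairs.add((a, b))

    def score_pair(self, upper: str, lower: str) -> float:
        for a, b in self._pairs:
            if lower == b and upper.endswith(a):
                return 1.0
        return 0.0


# ---------------------------------------------------------------------------
# monospace renderer
# ---------------------------------------------------------------------------


def _column_layout(table: LogicalTable, layout: LayoutSpec) -> list[tuple[float, int]]:
    """x offset and character capacity of each column."""
    caps = [
        max(1, max((len(row[j]) for row in table.cells), default=1))
        for j in range(table.n_cols)
    ]
    xs = []
    x = layout.margin
    for j, cap in enumerate(caps):
        xs.append((x, cap))
        x += cap * layout.char_width + layout.column_gap
    if x - layout.column_gap > layout.page_width - layout.margin:
        raise ValueError("table wider than page at this char_width")
    return xs


def render_table(
    table: LogicalTable,
    layout: LayoutSpec = LayoutSpec(),
    rng_seed: int = 0,
    image_scale: float = 2.0,
    rules: bool = True,
    page_offset: int = 0,
    first_line: int = 0,
) -> tuple[list[PageRecord], list[DetectionRecord], LogicalTable]:
    """Render a logical grid to character boxes plus detection fixtures.

    Monospace: column j starts at a fixed x offset; each grid row is one text
    line; glyphs in :data:`SUPERSCRIPT_CHARS` are raised by 0.4 line heights.
    Emits per page one ``table`` box, one ``table_column`` box per column, one
    ``table_row`` box per physical row and one ``table_cell`` box per grid
    position, in image pixels at ``image_scale`` pixels per point, with
    optional Gaussian jitter (sd ``layout.jitter_sd``, in points) on every
    detection coordinate.  Rows flow to the next page past
    ``max_lines_per_page``.  Returns (pages, detections, the input table).
    """
    rng = np.random.default_rng(rng_seed)
    cols = _column_layout(table, layout)
    glyph_h = 0.72 * layout.line_height
    rise = 0.4 * layout.line_height

    pages: dict[int, PageRecord] = {}
    img_w = int(round(layout.page_width * image_scale))
    img_h = int(round(layout.page_height * image_scale))

    def page_for(line_no: int) -> tuple[PageRecord, float]:
        p = page_offset + line_no // layout.max_lines_per_page
        page = pages.setdefault(
            p, PageRecord(p, layout.page_width, layout.page_height)
        )
        y = layout.margin + (line_no % layout.max_lines_per_page) * layout.line_height
        return page, y

    # glyph extents per (page, row) and per (page, col), for detection boxes
    row_extent: dict[tuple[int, int], list[float]] = {}
    col_extent: dict[tuple[int, int], list[float]] = {}

    for i, row in enumerate(table.cells):
        page, y = page_for(first_line + i)
        for j, cell in enumerate(row):
            x0, _cap = cols[j]
            for k, ch in enumerate(cell):
                gx = x0 + k * layout.char_width
                raised = ch in SUPERSCRIPT_CHARS
                gy = y - rise if raised else y
                page.char_boxes.append(
                    CharBox(ch, BBox(gx, gy, gx + layout.char_width, gy + glyph_h), page.page_index)
                )
                for ext, key in (
                    (row_extent, (page.page_index, i)),
                    (col_extent, (page.page_index, j)),
                ):
                    cur = ext.setdefault(key, [gx, gy, gx + layout.char_width, gy + glyph_h])
                    cur[0] = min(cur[0], gx)
                    cur[1] = min(cur[1], gy)
                    cur[2] = max(cur[2], gx + layout.char_width)
                    cur[3] = max(cur[3], gy + glyph_h)
            # remember the row band even for empty cells
            row_extent.setdefault((page.page_index, i), [cols[0][0], y, cols[0][0] + 1e-3, y + glyph_h])

    detections: list[DetectionRecord] = []

    def emit(label: str, page_index: int, x0, y0, x1, y1, score=0.9):
        if layout.jitter_sd > 0:
            x0, y0, x1, y1 = (
                v + layout.jitter_sd * rng.standard_normal() for v in (x0, y0, x1, y1)
            )
        px = [v * image_scale for v in (x0, y0, x1, y1)]
        px[0], px[2] = sorted((max(0.0, px[0]), min(float(img_w), px[2])))
        px[1], px[3] = sorted((max(0.0, px[1]), min(float(img_h), px[3])))
        if px[2] - px[0] < 1e-6:
            px[2] = px[0] + 1e-3
        if px[3] - px[1] < 1e-6:
            px[3] = px[1] + 1e-3
        detections.append(
            DetectionRecord(label, score, BBox(*px), page_index, img_w, img_h)
        )

    for p, page in sorted(pages.items()):
        rows_here = sorted(i for (pp, i) in row_extent if pp == p)
        if not rows_here:
            continue
        ext = [row_extent[(p, i)] for i in rows_here]
        tx0 = min(e[0] for e in ext) - 2
        ty0 = min(e[1] for e in ext) - 2
        tx1 = max(e[2] for e in ext) + 2
        ty1 = max(e[3] for e in ext) + 2
        emit("table", p, tx0, ty0, tx1, ty1, score=0.95)
        for j in range(table.n_cols):
            key = (p, j)
            if key not in col_extent:
                continue
            cx0, _, cx1, _ = col_extent[key]
            emit("table_column", p, cx0 - 1, ty0, cx1 + 1, ty1)
        for i in rows_here:
            rx0, ry0, rx1, ry1 = row_extent[(p, i)]
            emit("table_row", p, tx0, ry0 - 1, tx1, ry1 + 1)
            for j in range(table.n_cols):
                key = (p, j)
                if key not in col_extent:
                    continue
                cx0, _, cx1, _ = col_extent[key]
                emit("table_cell", p, cx0 - 1, ry0 - 1, cx1 + 1, ry1 + 1, score=0.85)
        if rules:
            for yy in (ty0, ty1):
                page.graphics.append(
                    GraphicsLine("horizontal", tx0, yy, tx1, yy + 0.4, page_index=p)
                )
            page.graphics.append(
                GraphicsLine("vertical", tx0, ty0, tx0 + 0.4, ty1, page_index=p)
            )

    return [pages[k] for k in sorted(pages)], detections, table


# ---------------------------------------------------------------------------
# documents for the page detector
# ---------------------------------------------------------------------------

_PROSE = (
    "the of and to in for with results methods analysis samples were was "
    "observed measured using between after before significant protein cells "
    "expression data figure shown mice brain tissue imaging level increase "
    "decrease control group treated model study experiments performed"
).split()


@dataclass
class SyntheticDocument:
    """A rendered multi-page document with known table placement."""

    pages: list[PageRecord]
    detections: list[DetectionRecord]
    gold_tables: list[LogicalTable]
    table_pages: list[int]
    #: per page index, the vertical band (y0, y1) occupied by table glyphs
    table_regions: dict[int, tuple[float, float]]


def generate_document(
    rng_seed: int,
    n_pages: int = 5,
    table_page: int | None = 3,
    table_rows: int = 8,
    layout: LayoutSpec = LayoutSpec(),
    overflow: bool = False,
) -> SyntheticDocument:
    """Build a document of prose pages with (optionally) one resource table.

    Prose lines are drawn from a small vocabulary and rendered with the same
    monospace geometry as tables; the table page additionally carries the
    rendered resource table, its detection boxes and its horizontal rules.
    """
    rng = np.random.default_rng(rng_seed)
    pages: list[PageRecord] = []
    detections: list[DetectionRecord] = []
    gold_tables: list[LogicalTable] = []
    table_regions: dict[int, tuple[float, float]] = {}

    for p in range(n_pages):
        page = PageRecord(p, layout.page_width, layout.page_height)
        n_lines = int(rng.integers(18, 30))
        reserved = range(4, 4 + table_rows + 2) if p == table_page else ()
        for ln in range(n_lines):
            if ln in reserved:
                continue
            y = layout.margin + ln * layout.line_height
            x = layout.margin
            n_words = int(rng.integers(6, 12))
            for w in range(n_words):
                word = str(rng.choice(_PROSE))
                for ch in word + " ":
                    page.char_boxes.append(
                        CharBox(
                            ch,
                            BBox(x, y, x + layout.char_width, y + 0.72 * layout.line_height),
                            p,
                        )
                    )
                    x += layout.char_width
        pages.append(page)

    if table_page is not None and 0 <= table_page < n_pages:
        table = generate_resource_table(
            table_rows, int(rng.integers(0, 2**31)), overflow=overflow
        )
        t_pages, t_dets, gold = render_table(
            table, layout, rng_seed=int(rng.integers(0, 2**31)),
            page_offset=table_page, first_line=4,
        )
        assert len(t_pages) == 1, "table must fit one page in document fixtures"
        host = pages[table_page]
        host.char_boxes.extend(
            CharBox(cb.glyph, cb.bbox, table_page) for cb in t_pages[0].char_boxes
        )
        host.graphics.extend(t_pages[0].graphics)
        detections.extend(t_dets)
        gold_tables.append(gold)
        ys = [cb.bbox for cb in t_pages[0].char_boxes]
        table_regions[table_page] = (min(b.y_min for b in ys), max(b.y_max for b in ys))

    return SyntheticDocument(
        pages=pages,
        detections=detections,
        gold_tables=gold_tables,
        table_pages=[table_page] if table_page is not None and 0 <= table_page < n_pages else [],
        table_regions=table_regions,
    )
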