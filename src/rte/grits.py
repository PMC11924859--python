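"""Grid table similarity (GriTS) metrics.

GriTS scores a predicted table B against a ground-truth table A by finding
order-preserving row and column selections of both grids (the most similar
2-D substructures), summing a per-cell similarity f over the aligned cells,
and normalizing F-measure style:

    GriTS_f   = 2 * sum(f) / (|A| + |B|)
    GriTS-P_f = sum(f) / |B|
    GriTS-R_f = sum(f) / |A|

with |.| counting grid cells.  Three similarity functions are provided:

* content  — longest-common-subsequence length over the ground-truth length;
* topology — IoU of the cells' span rectangles, expressed relative to each
  cell's own grid position (simple cells are unit squares, so two simple
  cells always score 1);
* location — IoU of the physical cell boxes, available only when both tables
  carry them.

The exact 2-D alignment is NP-hard in general.  :func:`best_alignment`
dispatches: when one axis admits a manageable number of order-preserving
selections (always true for 3-column resource tables), that axis is
enumerated and the other solved by sequence-alignment DP — provably optimal;
otherwise the factored iterative dynamic program of the GriTS reference
(columns aligned inside a row-pair score, rows aligned over those scores,
alternated to a fixed point from both a row-first and a column-first start)
approximates the optimum.  :func:`brute_force_alignment` is the independent
double-enumeration oracle used by the tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core_io import BBox, LogicalTable

__all__ = [
    "content_similarity",
    "topology_similarity",
    "location_similarity",
    "lcs_length",
    "Alignment",
    "GriTSReport",
    "best_alignment",
    "brute_force_alignment",
    "grits",
    "grits_report",
    "align_tables_by_vocab",
]


# ---------------------------------------------------------------------------
# cell similarity functions
# ---------------------------------------------------------------------------


@lru_cache(maxsize=200_000)
def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence (bit-parallel over words)."""
    if not a or not b:
        return 0
    if a == b:
        return len(a)
    n = len(a)
    masks: dict[str, int] = {}
    for i, ch in enumerate(a):
        masks[ch] = masks.get(ch, 0) | (1 << i)
    full = (1 << n) - 1
    v = full
    for ch in b:
        u = v & masks.get(ch, 0)
        v = ((v + u) | (v - u)) & full
    return n - bin(v).count("1")


def content_similarity(gt_cell: str, pred_cell: str) -> float:
    """LCS(gt, pred) / len(gt); 1 when both empty, 0 when only gt is empty."""
    if not gt_cell:
        return 1.0 if not pred_cell else 0.0
    return lcs_length(gt_cell, pred_cell) / len(gt_cell)


def _rect_iou(a: tuple[float, float, float, float], b: tuple[float, float, float, float]) -> float:
    ix = min(a[1], b[1]) - max(a[0], b[0])
    iy = min(a[3], b[3]) - max(a[2], b[2])
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    area_a = (a[1] - a[0]) * (a[3] - a[2])
    area_b = (b[1] - b[0]) * (b[3] - b[2])
    if area_a <= 0 or area_b <= 0:
        raise ValueError("degenerate span rectangle")
    return inter / (area_a + area_b - inter)


def topology_similarity(
    gt_rel_span: tuple[float, float, float, float],
    pred_rel_span: tuple[float, float, float, float],
) -> float:
    """IoU of grid-span rectangles given relative to the cells' positions."""
    return _rect_iou(gt_rel_span, pred_rel_span)


def location_similarity(gt_bbox: BBox | None, pred_bbox: BBox | None) -> float:
    """IoU of physical cell boxes; two absent boxes agree, one absent scores 0."""
    if gt_bbox is None and pred_bbox is None:
        return 1.0
    if gt_bbox is None or pred_bbox is None:
        return 0.0
    return gt_bbox.iou(pred_bbox)


def _relative_span(table: LogicalTable, i: int, j: int) -> tuple[float, float, float, float]:
    s = table.span_at(i, j)
    return (s.row_start - i, s.row_end - i, s.col_start - j, s.col_end - j)


def _sim_tensor(a: LogicalTable, b: LogicalTable, f: str) -> np.ndarray:
    """Sim[i, k, j, l] = f(A cell (i,j), B cell (k,l))."""
    ra, ca, rb, cb = a.n_rows, a.n_cols, b.n_rows, b.n_cols
    sim = np.zeros((ra, rb, ca, cb))
    if f == "content":
        for i in range(ra):
            for j in range(ca):
                gt = a.cells[i][j]
                for k in range(rb):
                    for l in range(cb):
                        sim[i, k, j, l] = content_similarity(gt, b.cells[k][l])
    elif f == "topology":
        for i in range(ra):
            for j in range(ca):
                sa = _relative_span(a, i, j)
                for k in range(rb):
                    for l in range(cb):
                        sim[i, k, j, l] = topology_similarity(sa, _relative_span(b, k, l))
    elif f == "location":
        if a.cell_boxes is None or b.cell_boxes is None:
            raise ValueError("location similarity needs cell boxes on both tables")
        for i in range(ra):
            for j in range(ca):
                for k in range(rb):
                    for l in range(cb):
                        sim[i, k, j, l] = location_similarity(
                            a.cell_boxes[i][j], b.cell_boxes[k][l]
                        )
    else:
        raise ValueError(f"unknown similarity function {f!r}")
    return sim


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """Order-preserving row and column index pairings between A and B."""

    row_pairs: tuple[tuple[int, int], ...]
    col_pairs: tuple[tuple[int, int], ...]
    score: float

    def __post_init__(self) -> None:
        for pairs in (self.row_pairs, self.col_pairs):
            for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]):
                if not (a1 < a2 and b1 < b2):
                    raise ValueError("alignment maps must be strictly increasing")


def _seq_align(gain: np.ndarray) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Monotone sequence alignment maximizing the sum of non-negative gains."""
    n, m = gain.shape
    dp = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = max(dp[i - 1, j], dp[i, j - 1], dp[i - 1, j - 1] + gain[i - 1, j - 1])
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        if dp[i, j] == dp[i - 1, j]:
            i -= 1
        elif dp[i, j] == dp[i, j - 1]:
            j -= 1
        else:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
    return float(dp[n, m]), tuple(reversed(pairs))


def _pairs_score(sim: np.ndarray, row_pairs, col_pairs) -> float:
    return float(
        sum(sim[i, k, j, l] for i, k in row_pairs for j, l in col_pairs)
    )


#: the exact path is taken when one axis admits at most this many
#: order-preserving selections (given a fixed selection on that axis the other
#: axis is solved exactly by DP, so only one axis needs enumeration).
EXACT_ENUM_LIMIT = 3500


def _n_selections(n: int, m: int) -> int:
    return math.comb(n + m, n)


def _axis_selections(n: int, m: int):
    yield ()
    for k in range(1, min(n, m) + 1):
        for sa in itertools.combinations(range(n), k):
            for sb in itertools.combinations(range(m), k):
                yield tuple(zip(sa, sb))


def _exact_alignment(sim: np.ndarray) -> Alignment:
    """Provably optimal alignment by enumerating the cheaper axis.

    For each order-preserving selection on the enumerated axis, the optimal
    selection on the other axis follows from a single sequence-alignment DP,
    so the enumeration of only one axis already covers the full search space.
    """
    ra, rb, ca, cb = sim.shape
    enum_cols = _n_selections(ca, cb) <= _n_selections(ra, rb)
    best_score = -1.0
    best_rows: tuple = ()
    best_cols: tuple = ()
    if enum_cols:
        for cols in _axis_selections(ca, cb):
            gain = np.zeros((ra, rb))
            for j, l in cols:
                gain += sim[:, :, j, l]
            _, rows = _seq_align(gain)
            score = _pairs_score(sim, rows, cols)  # canonical summation order
            if score > best_score:
                best_score, best_rows, best_cols = score, rows, cols
    else:
        for rows in _axis_selections(ra, rb):
            gain = np.zeros((ca, cb))
            for i, k in rows:
                gain += sim[i, k]
            _, cols = _seq_align(gain)
            score = _pairs_score(sim, rows, cols)
            if score > best_score:
                best_score, best_rows, best_cols = score, rows, cols
    return Alignment(tuple(best_rows), tuple(best_cols), float(best_score))


def _factored_alignment(sim: np.ndarray) -> Alignment:
    """Factored iterative DP (approximate 2-D optimum).

    A first pass scores every row pair by an inner column alignment and
    aligns rows on those scores; a symmetric pass starts from columns.  From
    each start, column-given-rows and rows-given-columns passes alternate to
    a fixed point (at most 10 iterations); the best-scoring alignment seen is
    returned.
    """
    ra, rb, ca, cb = sim.shape

    def alternate(row_pairs) -> Alignment:
        best: Alignment | None = None
        prev = None
        for _ in range(10):
            col_gain = np.zeros((ca, cb))
            for i, k in row_pairs:
                col_gain += sim[i, k]
            _, col_pairs = _seq_align(col_gain)
            row_gain = np.zeros((ra, rb))
            for j, l in col_pairs:
                row_gain += sim[:, :, j, l]
            _, row_pairs = _seq_align(row_gain)
            cand = Alignment(
                tuple(row_pairs), tuple(col_pairs), _pairs_score(sim, row_pairs, col_pairs)
            )
            if best is None or cand.score > best.score:
                best = cand
            state = (tuple(row_pairs), tuple(col_pairs))
            if state == prev:
                break
            prev = state
        assert best is not None
        return best

    # row-first start
    row_gain = np.zeros((ra, rb))
    for i in range(ra):
        for k in range(rb):
            row_gain[i, k], _ = _seq_align(sim[i, k])
    _, row_pairs = _seq_align(row_gain)
    best = alternate(row_pairs)

    # column-first start
    col_gain = np.zeros((ca, cb))
    for j in range(ca):
        for l in range(cb):
            col_gain[j, l], _ = _seq_align(sim[:, :, j, l])
    _, col_pairs = _seq_align(col_gain)
    row_gain = np.zeros((ra, rb))
    for j, l in col_pairs:
        row_gain += sim[:, :, j, l]
    _, row_pairs = _seq_align(row_gain)
    cand = alternate(row_pairs)
    return cand if cand.score > best.score else best


def best_alignment(
    a: LogicalTable, b: LogicalTable, f: str = "content", exact: bool | None = None
) -> Alignment:
    """Best order-preserving 2-D substructure alignment of A and B.

    The general problem is NP-hard; the factored iterative DP is used for
    large grids, while grids with a cheaply enumerable axis (at most
    :data:`EXACT_ENUM_LIMIT` selections — always the case for the 3-column
    key-resource shape) are solved exactly, so the approximation never
    degrades desk-scale comparisons.  ``exact`` forces one path or the other.
    """
    if a.n_cells == 0 or b.n_cells == 0:
        raise ValueError("cannot align an empty table")
    sim = _sim_tensor(a, b, f)
    if exact is None:
        exact = (
            min(_n_selections(a.n_rows, b.n_rows), _n_selections(a.n_cols, b.n_cols))
            <= EXACT_ENUM_LIMIT
        )
    if exact:
        return _exact_alignment(sim)
    return _factored_alignment(sim)


def brute_force_alignment(a: LogicalTable, b: LogicalTable, f: str = "content") -> Alignment:
    """Exhaustive optimum over all order-preserving row/column selections.

    Exponential — intended as an oracle for tables up to a few rows/columns.
    """
    if a.n_cells == 0 or b.n_cells == 0:
        raise ValueError("cannot align an empty table")
    sim = _sim_tensor(a, b, f)
    ra, rb, ca, cb = a.n_rows, b.n_rows, a.n_cols, b.n_cols

    def selections(n: int, m: int):
        yield ()
        for k in range(1, min(n, m) + 1):
            for sa in itertools.combinations(range(n), k):
                for sb in itertools.combinations(range(m), k):
                    yield tuple(zip(sa, sb))

    best_score = -1.0
    best_rows: tuple = ()
    best_cols: tuple = ()
    col_options = list(selections(ca, cb))
    for rows in selections(ra, rb):
        for cols in col_options:
            s = _pairs_score(sim, rows, cols)
            if s > best_score:
                best_score, best_rows, best_cols = s, rows, cols
    return Alignment(best_rows, best_cols, best_score)


# ---------------------------------------------------------------------------
# the metric
# ---------------------------------------------------------------------------


def grits(a: LogicalTable, b: LogicalTable, f: str = "content") -> tuple[float, float, float]:
    """(GriTS_f, GriTS-P_f, GriTS-R_f) for ground truth ``a`` and prediction ``b``.

    Two empty tables are defined to agree perfectly; if exactly one is empty
    all three values are 0.
    """
    if a.n_cells == 0 and b.n_cells == 0:
        return 1.0, 1.0, 1.0
    if a.n_cells == 0 or b.n_cells == 0:
        return 0.0, 0.0, 0.0
    total = best_alignment(a, b, f).score
    return (
        2.0 * total / (a.n_cells + b.n_cells),
        total / b.n_cells,
        total / a.n_cells,
    )


@dataclass
class GriTSReport:
    """Per-similarity GriTS scores for one (ground truth, prediction) pair."""

    content: tuple[float, float, float]
    topology: tuple[float, float, float]
    location: tuple[float, float, float] | None
    n_gt_cells: int
    n_pred_cells: int

    def as_dict(self) -> dict:
        out = {
            "grits_cont": self.content[0],
            "grits_p_cont": self.content[1],
            "grits_r_cont": self.content[2],
            "grits_top": self.topology[0],
            "grits_p_top": self.topology[1],
            "grits_r_top": self.topology[2],
            "n_gt_cells": self.n_gt_cells,
            "n_pred_cells": self.n_pred_cells,
        }
        if self.location is not None:
            out.update(
                grits_loc=self.location[0],
                grits_p_loc=self.location[1],
                grits_r_loc=self.location[2],
            )
        return out


def grits_report(a: LogicalTable, b: LogicalTable) -> GriTSReport:
    """Content and topology GriTS, plus location when both tables carry boxes."""
    loc = None
    if a.cell_boxes is not None and b.cell_boxes is not None:
        loc = grits(a, b, "location")
    return GriTSReport(
        content=grits(a, b, "content"),
        topology=grits(a, b, "topology"),
        location=loc,
        n_gt_cells=a.n_cells,
        n_pred_cells=b.n_cells,
    )


# ---------------------------------------------------------------------------
# gold <-> predicted table pairing by vocabulary overlap
# ---------------------------------------------------------------------------


def _vocab(table: LogicalTable) -> set[str]:
    return {tok.lower() for row in table.cells for cell in row for tok in cell.split()}


def align_tables_by_vocab(
    pred_tables: list[LogicalTable],
    gold_tables: list[LogicalTable],
    threshold: float = 0.40,
) -> list[tuple[int, int, float]]:
    """Greedy best-first (pred, gold) pairing on vocabulary overlap.

    Overlap is |V_pred & V_gold| / |V_gold|; pairs must exceed the threshold
    strictly, and each table is matched at most once.  Returns
    (pred_index, gold_index, overlap) triples.
    """
    cand = []
    gold_vocabs = [_vocab(t) for t in gold_tables]
    pred_vocabs = [_vocab(t) for t in pred_tables]
    for gi, vg in enumerate(gold_vocabs):
        for pi, vp in enumerate(pred_vocabs):
            overlap = len(vp & vg) / len(vg) if vg else 0.0
            cand.append((overlap, pi, gi))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    out = []
    for overlap, pi, gi in cand:
        if overlap <= threshold or pi in used_p or gi in used_g:
            continue
        used_p.add(pi)
        used_g.add(gi)
        out.append((pi, gi, overlap))
    return out
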