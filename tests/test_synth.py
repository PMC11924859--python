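import itertools
import re

import pytest
from hypothesis import given, settings, strategies as st

from rte.core_io import LogicalTable
from rte.synth import (
    HEADER,
    LayoutSpec,
    OverflowConfig,
    allocate_column_widths,
    generate_resource_table,
    join_fragments,
    merge_row_groups,
    render_table,
    select_for_overflow,
    simulate_overflow,
    split_cell,
)


def table_with_rows(*row_lengths_per_col):
    """Helper: a table whose cells are 'a' * length."""
    return LogicalTable(cells=[["a" * n for n in row] for row in row_lengths_per_col])


class TestGenerator:
    def test_deterministic(self):
        assert generate_resource_table(5, 7) == generate_resource_table(5, 7)

    def test_rrid_pattern(self):
        t = generate_resource_table(20, 3)
        ids = " ".join(row[2] for row in t.cells[1:])
        found = re.findall(r"RRID:[A-Z]+_[A-Za-z0-9]+", ids)
        assert found  # identifiers follow the RRID shape

    def test_shape_and_header(self):
        t = generate_resource_table(4, 0)
        assert (t.n_rows, t.n_cols, t.n_header_rows) == (5, 3, 1)
        assert t.cells[0] == HEADER

    def test_overflow_guarantee(self):
        for seed in range(10):
            t = generate_resource_table(3, seed, overflow=True)
            assert any(sum(len(c) for c in row) > 90 for row in t.cells)

    def test_no_rows_rejected(self):
        with pytest.raises(ValueError):
            generate_resource_table(0, 1)

    def test_superscript_markers(self):
        t = generate_resource_table(20, 1, superscript_prob=1.0)
        assert any(any(ch in "†‡§" for ch in row[0]) for row in t.cells[1:])


class TestSelection:
    def test_all_rows_at_most_90_not_selected(self):
        t = table_with_rows([30, 30, 30])
        assert select_for_overflow(t)[0] is False

    def test_longest_95_selected_narrow(self):
        t = table_with_rows([30, 35, 30], [10, 10, 10])
        assert select_for_overflow(t) == (True, 80)

    def test_longest_150_selected_wide(self):
        t = table_with_rows([50, 50, 50])
        assert select_for_overflow(t) == (True, 90)


def largest_remainder_oracle(weights, total):
    """Independent enumeration oracle: all integer vectors summing to total
    that minimize total deviation from exact proportionality (tie set)."""
    n = len(weights)
    exact = [total * w / sum(weights) for w in weights]
    best, best_err = [], None
    for combo in itertools.product(range(total + 1), repeat=n):
        if sum(combo) != total or min(combo) < 1:
            continue
        err = sum(abs(c - e) for c, e in zip(combo, exact))
        if best_err is None or err < best_err - 1e-12:
            best, best_err = [combo], err
        elif abs(err - best_err) <= 1e-12:
            best.append(combo)
    return best


class TestWidthAllocation:
    def test_symmetry(self):
        t = table_with_rows([10, 10, 10], [20, 20, 20])
        assert allocate_column_widths(t, 90) == [30, 30, 30]

    def test_exact_proportionality(self):
        # single row: sd = 0, weights are the lengths themselves
        t = table_with_rows([10, 20, 30])
        assert allocate_column_widths(t, 60) == [10, 20, 30]

    def test_largest_remainder_against_enumeration(self):
        t = table_with_rows([1, 1, 1])
        widths = allocate_column_widths(t, 10)
        assert sum(widths) == 10
        assert max(widths) - min(widths) <= 1
        assert tuple(widths) in largest_remainder_oracle([1, 1, 1], 10)

    def test_width_smaller_than_columns_rejected(self):
        with pytest.raises(ValueError):
            allocate_column_widths(table_with_rows([5, 5, 5]), 2)

    def test_every_column_at_least_one(self):
        t = table_with_rows([100, 1, 1])
        widths = allocate_column_widths(t, 20)
        assert min(widths) >= 1 and sum(widths) == 20


class TestSplitCell:
    @pytest.mark.parametrize(
        "content,width,expected",
        [
            ("aaa bbb ccc", 4, ["aaa", "bbb", "ccc"]),
            ("abcdefgh", 3, ["abc", "def", "gh"]),
            ("short", 10, ["short"]),
            ("a b", 3, ["a b"]),
            ("", 5, [""]),
        ],
    )
    def test_examples(self, content, width, expected):
        assert split_cell(content, width) == expected

    def test_width_below_one_rejected(self):
        with pytest.raises(ValueError):
            split_cell("x", 0)

    @settings(max_examples=100, deadline=None)
    @given(
        st.text(alphabet="ab RID:_0", min_size=0, max_size=60),
        st.integers(min_value=1, max_value=12),
    )
    def test_fragments_fit_and_reassemble(self, content, width):
        frags = split_cell(content, width)
        assert all(len(f) <= width for f in frags)
        # joining at space-split points with spaces, hard splits directly,
        # reproduces the content: verify via character conservation and,
        # when no word exceeds the width, exact space-join equality
        assert "".join(frags).replace(" ", "") == content.replace(" ", "")
        if all(len(w) <= width for w in content.split(" ")):
            assert join_fragments(frags) == content


class TestSimulateOverflow:
    def test_three_fragments_two_positives(self):
        # single 200-char column: W = 90, so the cell splits into 3 fragments
        content = " ".join(["word"] * 40)
        t = LogicalTable(cells=[[content]])
        overseg, groups, inst = simulate_overflow(t, OverflowConfig(seed=0))
        pos = [i for i in inst if i.label == 1]
        assert len(groups[0]) == 3
        assert len(pos) == len(groups[0]) - 1  # pairs = fragments - 1
        assert [i.lower for i in pos] == [overseg.cells[1][0], overseg.cells[2][0]]

    def test_roundtrip_over_seeds(self):
        for seed in range(25):
            t = generate_resource_table(6, seed, overflow=True)
            overseg, groups, _ = simulate_overflow(t, OverflowConfig(seed=seed))
            assert merge_row_groups(overseg, groups) == t

    def test_no_overflow_no_positives(self):
        t = table_with_rows([10, 10, 10], [12, 12, 12])
        _, groups, inst = simulate_overflow(t, OverflowConfig(seed=0))
        assert [i for i in inst if i.label == 1] == []
        assert all(len(g) == 1 for g in groups)

    def test_non_overflowing_cells_on_first_physical_row(self):
        t = generate_resource_table(6, 11, overflow=True)
        overseg, groups, _ = simulate_overflow(t, OverflowConfig(seed=11))
        for gi, group in enumerate(groups):
            for j in range(3):
                for k in group[1:]:
                    cell = overseg.cells[k][j]
                    # continuation rows carry only fragments of split cells
                    if cell:
                        assert len(t.cells[gi][j]) > 0

    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    def test_negative_ratio_control(self, ratio):
        t = generate_resource_table(12, 5, overflow=True)
        # candidate pool: neighboring same-column pairs where neither cell overflows
        _, total_width = select_for_overflow(t)
        widths = allocate_column_widths(t, total_width)
        candidates = sum(
            1
            for i in range(t.n_rows - 1)
            for j in range(t.n_cols)
            if len(t.cells[i][j]) <= widths[j] and len(t.cells[i + 1][j]) <= widths[j]
        )
        _, _, inst = simulate_overflow(t, OverflowConfig(seed=5, negative_ratio=ratio))
        pos = sum(1 for i in inst if i.label == 1)
        neg = sum(1 for i in inst if i.label == 0)
        assert neg == min(candidates, round(ratio * pos))


class TestRenderer:
    def test_deterministic(self):
        t = generate_resource_table(4, 2, overflow=False)
        a = render_table(t, rng_seed=9)
        b = render_table(t, rng_seed=9)
        assert a[0][0].char_boxes == b[0][0].char_boxes
        assert a[1] == b[1]

    def test_noiseless_column_boxes_bound_their_glyphs(self):
        t = generate_resource_table(3, 4, overflow=False)
        pages, dets, _ = render_table(t, LayoutSpec(jitter_sd=0.0), rng_seed=0)
        page = pages[0]
        scale = page.page_width / dets[0].image_width
        cols = [d for d in dets if d.label == "table_column"]
        assert len(cols) == 3
        for d in cols:
            x0, x1 = d.bbox.x_min * scale, d.bbox.x_max * scale
            inside = [c for c in page.char_boxes if x0 <= c.bbox.x_center <= x1]
            assert inside  # each column box contains glyphs

    def test_page_break(self):
        t = generate_resource_table(40, 3, overflow=False)
        pages, dets, _ = render_table(
            t, LayoutSpec(max_lines_per_page=30), rng_seed=0
        )
        assert [p.page_index for p in pages] == [0, 1]
        assert {d.page_index for d in dets if d.label == "table"} == {0, 1}

    def test_too_wide_rejected(self):
        t = LogicalTable(cells=[["x" * 300]])
        with pytest.raises(ValueError):
            render_table(t, LayoutSpec())

    def test_superscript_glyph_raised(self):
        t = LogicalTable(cells=[["ab†", "c", "d"]])
        pages, _, _ = render_table(t, rng_seed=0)
        boxes = {c.glyph: c.bbox for c in pages[0].char_boxes}
        assert boxes["†"].y_min < boxes["a"].y_min
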