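import json

import pytest
from hypothesis import given, settings, strategies as st

from rte.core_io import (
    BBox,
    CellSpan,
    CharBox,
    DetectionRecord,
    GraphicsLine,
    LogicalTable,
    PageRecord,
    ValidationError,
    read_charboxes,
    read_detections,
    read_jats_tables,
    read_table,
    write_charboxes,
    write_detections,
    write_table,
)

FLY = "Pry[+t7.2]=hsFLP12, y[1] w[*]; Pw[+mW.hs]=GawBap[md544]"


class TestGeometry:
    def test_bbox_invariants(self):
        with pytest.raises(ValidationError):
            BBox(5, 0, 4, 1)  # x_min > x_max
        with pytest.raises(ValidationError):
            BBox(0, 2, 1, 2)  # empty y interval
        with pytest.raises(ValidationError):
            BBox(0, 0, float("nan"), 1)

    def test_charbox_glyph_length(self):
        with pytest.raises(ValidationError):
            CharBox("ab", BBox(0, 0, 1, 1))

    def test_graphics_line_orientation(self):
        GraphicsLine("horizontal", 0, 5, 100, 5.2)
        with pytest.raises(ValidationError):
            GraphicsLine("diagonal", 0, 0, 1, 1)
        with pytest.raises(ValidationError):
            GraphicsLine("horizontal", 0, 0, 1, 50)

    def test_detection_validation(self):
        box = BBox(10, 10, 20, 20)
        DetectionRecord("table", 0.9, box, 0, 100, 100)
        with pytest.raises(ValidationError):
            DetectionRecord("figure", 0.9, box, 0, 100, 100)
        with pytest.raises(ValidationError):
            DetectionRecord("table", 1.2, box, 0, 100, 100)
        with pytest.raises(ValidationError):
            DetectionRecord("table", 0.9, BBox(90, 90, 120, 95), 0, 100, 100)


class TestCharboxesIO:
    def test_roundtrip_two_glyphs(self, tmp_path):
        page = PageRecord(
            0, 612, 792,
            char_boxes=[
                CharBox("A", BBox(10, 10, 16, 20), 0),
                CharBox("b", BBox(16, 10, 22, 20), 0),
            ],
            graphics=[GraphicsLine("horizontal", 10, 30, 100, 30.2, 0)],
        )
        path = tmp_path / "chars.jsonl"
        write_charboxes([page], path)
        pages = read_charboxes(path)
        assert len(pages) == 1 and len(pages[0].char_boxes) == 2
        assert pages[0].text == "Ab"
        assert pages[0].graphics[0].orientation == "horizontal"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert read_charboxes(path) == []

    def test_per_char_dialect(self, tmp_path):
        path = tmp_path / "chars.jsonl"
        path.write_text(
            '{"page": 1, "c": "µ", "x0": 1, "y0": 2, "x1": 3, "y1": 4}\n'
            '{"page": 0, "c": "x", "x0": 1, "y0": 2, "x1": 3, "y1": 4}\n'
        )
        pages = read_charboxes(path)
        assert [p.page_index for p in pages] == [0, 1]
        assert pages[1].char_boxes[0].glyph == "µ"

    def test_invalid_bbox_names_record(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"page": 0, "c": "x", "x0": 5, "y0": 2, "x1": 3, "y1": 4}\n')
        with pytest.raises(ValidationError, match="line 1"):
            read_charboxes(path)

    def test_malformed_json_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"page": 0, "chars": []}\n{oops\n')
        with pytest.raises(ValueError, match="line 2"):
            read_charboxes(path)

    def test_flip_y_converts_origin(self, tmp_path):
        path = tmp_path / "chars.jsonl"
        path.write_text(
            '{"page": 0, "w": 100.0, "h": 200.0, '
            '"chars": [{"c": "x", "x0": 0, "y0": 190, "x1": 5, "y1": 200}]}\n'
        )
        cb = read_charboxes(path, flip_y=True)[0].char_boxes[0]
        assert (cb.bbox.y_min, cb.bbox.y_max) == (0.0, 10.0)


class TestDetectionsIO:
    def test_roundtrip_and_order(self, tmp_path):
        recs = [
            DetectionRecord("table_column", 0.8, BBox(1, 1, 5, 9), 0, 10, 10),
            DetectionRecord("table", 0.99, BBox(0, 0, 10, 10), 0, 10, 10),
        ]
        path = tmp_path / "det.json"
        write_detections(recs, path)
        assert read_detections(path) == recs

    def test_unknown_label_lists_allowed(self, tmp_path):
        path = tmp_path / "det.json"
        path.write_text(
            '[{"label": "figure", "score": 0.5, "page": 0, "img_w": 10, "img_h": 10,'
            ' "x0": 0, "y0": 0, "x1": 1, "y1": 1}]'
        )
        with pytest.raises(ValidationError, match="table_column"):
            read_detections(path)

    def test_score_out_of_range(self, tmp_path):
        path = tmp_path / "det.json"
        path.write_text(
            '[{"label": "table", "score": 1.2, "page": 0, "img_w": 10, "img_h": 10,'
            ' "x0": 0, "y0": 0, "x1": 1, "y1": 1}]'
        )
        with pytest.raises(ValidationError):
            read_detections(path)


class TestTableIO:
    @pytest.mark.parametrize("fmt", ["csv", "json", "html"])
    def test_roundtrip_special_characters(self, tmp_path, fmt):
        table = LogicalTable(
            cells=[["a,b", "x\ny"], [FLY, "µ † RRID:AB_12345"]],
            n_header_rows=1,
        )
        path = tmp_path / f"t.{fmt}"
        write_table(table, path, fmt)
        back = read_table(path, fmt)
        assert back.cells == table.cells
        if fmt != "csv":  # CSV cannot carry header metadata
            assert back.n_header_rows == table.n_header_rows

    def test_empty_table_roundtrip(self, tmp_path):
        path = tmp_path / "t.json"
        write_table(LogicalTable(cells=[]), path, "json")
        assert read_table(path, "json").cells == []

    def test_unsupported_format(self, tmp_path):
        with pytest.raises(ValueError):
            write_table(LogicalTable(cells=[["x"]]), tmp_path / "t.xlsx", "xlsx")

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.lists(st.text(alphabet=st.characters(blacklist_categories=("Cs",),
                                                    blacklist_characters="\r"),
                             max_size=12),
                     min_size=1, max_size=4),
            min_size=1, max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_json_roundtrip_is_exact_inverse(self, tmp_path_factory, rows):
        table = LogicalTable(cells=rows)
        path = tmp_path_factory.mktemp("prop") / "t.json"
        write_table(table, path, "json")
        assert read_table(path, "json").cells == rows


JATS = """<?xml version="1.0"?>
<article>
 <body>
  <table-wrap id="T1">
   <table>
    <thead><tr><th>Resource</th><th>Source</th><th>ID</th></tr></thead>
    <tbody>
     <tr><td>anti-GFAP</td><td>Abcam</td><td>RRID:AB_1</td></tr>
     <tr><td>DAPI</td><td>Sigma</td><td>Cat# D1</td></tr>
    </tbody>
   </table>
  </table-wrap>
 </body>
</article>
"""

JATS_SPAN = """<?xml version="1.0"?>
<article><body><table-wrap id="T2"><table>
 <tbody>
  <tr><td colspan="2">wide</td><td>c</td></tr>
  <tr><td>a</td><td>b</td><td>d</td></tr>
 </tbody>
</table></table-wrap></body></article>
"""


class TestJATS:
    def test_header_and_body_rows(self, tmp_path):
        path = tmp_path / "a.xml"
        path.write_text(JATS)
        tables = read_jats_tables(path)
        assert len(tables) == 1
        t = tables[0]
        assert (t.n_rows, t.n_cols, t.n_header_rows) == (3, 3, 1)
        assert t.cells[1] == ["anti-GFAP", "Abcam", "RRID:AB_1"]

    def test_colspan_recorded_grid_rectangular(self, tmp_path):
        # hand expansion: row 0 is [wide, wide, c]; span covers (0,0)-(0,2)
        path = tmp_path / "b.xml"
        path.write_text(JATS_SPAN)
        t = read_jats_tables(path)[0]
        assert t.cells == [["wide", "wide", "c"], ["a", "b", "d"]]
        assert t.spans == [CellSpan(0, 1, 0, 2)]
        assert t.span_at(0, 1) == CellSpan(0, 1, 0, 2)
        assert t.span_at(1, 1) == CellSpan(1, 2, 1, 2)

    def test_file_without_tables(self, tmp_path):
        path = tmp_path / "c.xml"
        path.write_text("<article><body><p>no tables</p></body></article>")
        assert read_jats_tables(path) == []


class TestLogicalTable:
    def test_ragged_rejected(self):
        with pytest.raises(ValidationError):
            LogicalTable(cells=[["a", "b"], ["c"]])

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValidationError):
            LogicalTable(
                cells=[["x", "x"], ["y", "z"]],
                spans=[CellSpan(0, 2, 0, 1), CellSpan(0, 1, 0, 2)],
            )
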