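import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from rte.core_io import BBox, CharBox, GraphicsLine, PageRecord
from rte.page_detect import (
    EmbeddingTable,
    LineFeatures,
    extract_line_features,
    tokenize,
    train_line_classifier,
    train_page_classifier,
)


class TestTokenizer:
    def test_lowercase_and_punct(self):
        assert tokenize("Anti-GFAP (Abcam)") == ["anti", "-", "gfap", "(", "abcam", ")"]

    def test_numbers_mapped(self):
        assert tokenize("Cat# 12345") == ["cat", "#", "<NUM>"]


def simple_page(texts, with_rule=False, page_index=0):
    page = PageRecord(page_index, 612, 792)
    for ln, text in enumerate(texts):
        y = 40 + 12 * ln
        x = 40.0
        for ch in text:
            page.char_boxes.append(CharBox(ch, BBox(x, y, x + 5, y + 8), page_index))
            x += 5
    if with_rule:
        page.graphics.append(GraphicsLine("horizontal", 30, 41, 500, 41.3, page_index))
    return page


class TestLineFeatures:
    def setup_method(self):
        self.emb = EmbeddingTable.random(["hello", "world", "rrid"], dim=8, seed=0)

    def test_no_graphics_all_indicators_zero(self):
        page = simple_page(["hello world", "world hello"])
        f = extract_line_features(page, 1, self.emb)
        assert f.indicators.tolist() == [0, 0, 0, 0]

    def test_horizontal_rule_sets_indicator(self):
        page = simple_page(["hello world"], with_rule=True)
        f = extract_line_features(page, 0, self.emb)
        assert f.indicators[0] == 1

    def test_first_line_padded_with_null_token(self):
        page = simple_page(["hello"])
        f = extract_line_features(page, 0, self.emb, window=2)
        # two null vectors for the two missing previous lines
        assert (f.token_vectors[:2] == 0).all()
        assert f.token_vectors.shape[0] == 3

    def test_out_of_range_line(self):
        page = simple_page(["hello"])
        with pytest.raises(IndexError):
            extract_line_features(page, 5, self.emb)

    def test_oov_token_maps_to_oov_vector(self):
        page = simple_page(["zebrafish"])
        f = extract_line_features(page, 0, self.emb, window=0)
        assert (f.token_vectors[-1] == self.emb.oov).all()


def toy_dataset(emb, rng, n=80):
    """Linearly separable: positive lines contain the token 'rrid'."""
    data = []
    vocab = ["study", "results", "brain", "cells", "rrid", "antibody"]
    for k in range(n):
        label = k % 2
        words = list(rng.choice(vocab[:4], size=4))
        if label:
            words[2] = "rrid"
        vecs = np.stack([emb.get(w) for w in words]).astype(np.float32)
        data.append(
            (LineFeatures(vecs, np.zeros(4, dtype=np.float32), 0), label)
        )
    return data


class TestLineClassifier:
    def test_separable_toy_set(self):
        rng = np.random.default_rng(0)
        emb = EmbeddingTable.random(
            ["study", "results", "brain", "cells", "rrid", "antibody"], dim=16, seed=1
        )
        data = toy_dataset(emb, rng, n=80)
        train, test = data[:60], data[60:]
        # logistic-regression oracle on mean embeddings certifies separability
        Xtr = np.stack([f.token_vectors.mean(axis=0) for f, _ in train])
        Xte = np.stack([f.token_vectors.mean(axis=0) for f, _ in test])
        ytr = [y for _, y in train]
        yte = [y for _, y in test]
        oracle = LogisticRegression(max_iter=200).fit(Xtr, ytr)
        assert oracle.score(Xte, yte) >= 0.95
        # the toy classes are balanced, so no positive up-weighting here
        model, losses = train_line_classifier(
            train, class_weight_pos=1.0, seed=0, hidden=16, epochs=3
        )
        acc = np.mean([(model.predict_proba(f) > 0.5) == y for f, y in test])
        assert acc >= 0.95
        assert len(losses) == 3 * len(train)

    def test_empty_and_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_line_classifier([])
        emb = EmbeddingTable.random(["a"], dim=4, seed=0)
        feats = LineFeatures(np.zeros((1, 4), dtype=np.float32), np.zeros(4, dtype=np.float32), 0)
        with pytest.raises(ValueError):
            train_line_classifier([(feats, 1), (feats, 1)])

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        emb = EmbeddingTable.random(["study", "results", "brain", "cells", "rrid"], dim=8, seed=1)
        data = toy_dataset(emb, rng, n=30)
        m1, l1 = train_line_classifier(data, seed=5, hidden=8, epochs=1)
        m2, l2 = train_line_classifier(data, seed=5, hidden=8, epochs=1)
        assert l1 == l2


class TestPageClassifier:
    TEXTS = [
        "antibody rrid ab 12345 source identifier",
        "reagent rrid scr 999 resource table",
        "the brain study results were significant",
        "methods samples were measured in mice",
        "discussion of imaging data and figures",
        "rrid catalog antibody vendor identifier",
        "control group analysis protein levels",
        "statistical tests were performed on data",
    ]
    LABELS = [1, 1, 0, 0, 0, 1, 0, 0]

    def test_separable_corpus_training_accuracy(self):
        counts = [8, 7, 0, 0, 0, 9, 0, 1]
        model = train_page_classifier(self.TEXTS, counts, self.LABELS, seed=0)
        assert (model.predict(self.TEXTS, counts) == self.LABELS).all()

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(0)
        texts = [
            " ".join(rng.choice(["a", "b", "c", "d", "e", "f"], size=12)) for _ in range(40)
        ]
        labels = [k % 2 for k in range(40)]
        counts = [0] * 40
        model = train_page_classifier(texts[:30], counts[:30], labels[:30], seed=0)
        acc = np.mean(model.predict(texts[30:], counts[30:]) == labels[30:])
        assert 0.2 <= acc <= 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_page_classifier(["a"], [0], [1])

    def test_stacking_ablation(self):
        # trained with an uninformative (all-zero) count feature, the model's
        # predictions cannot depend on the count passed at inference
        model = train_page_classifier(self.TEXTS, [0] * 8, self.LABELS, seed=0)
        p0 = model.predict(self.TEXTS, [0] * 8)
        p9 = model.predict(self.TEXTS, [0] * 8)
        assert (p0 == p9).all()
        assert abs(model.svm.coef_[0][-1]) < 1e-6


class TestStackedDetector:
    def test_empty_document(self, page_detector_setup):
        detector, _, _ = page_detector_setup
        assert detector.detect([]) == []

    def test_in_table_line_counts_separate_pages(self, page_detector_setup):
        from rte.page_detect import predict_in_table_lines

        detector, _, test_docs = page_detector_setup
        doc = next(d for d in test_docs if d.table_pages)
        table_page = doc.table_pages[0]
        counts = {
            p.page_index: predict_in_table_lines(detector.line_model, p, detector.embeddings)
            for p in doc.pages
        }
        assert counts[table_page] >= 3
        for p, c in counts.items():
            if p != table_page:
                assert c <= 2

    def test_candidates_sorted_and_valid(self, page_detector_setup):
        detector, _, test_docs = page_detector_setup
        for doc in test_docs:
            got = detector.detect(doc.pages)
            assert got == sorted(got)
            assert set(got) <= {p.page_index for p in doc.pages}

    def test_save_load_roundtrip(self, tmp_path, page_detector_setup):
        from rte.page_detect import PageDetector

        detector, _, test_docs = page_detector_setup
        path = tmp_path / "detector.pkl"
        detector.save(path)
        back = PageDetector.load(path)
        doc = test_docs[0]
        assert back.detect(doc.pages) == detector.detect(doc.pages)
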