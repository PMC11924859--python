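"""Shared fixtures.

The expensive artifacts (pretrained tiny language model, fine-tuned merge
classifier, trained page detector) are session-scoped so the unit tests and
the acceptance tests share one training run each.
"""

from __future__ import annotations

import pytest

from rte.pipeline import (
    make_overflow_fixture,
    synthetic_page_corpus,
    train_page_detector,
)
from rte.synth import OverflowConfig, generate_resource_table, simulate_overflow
from rte.table_lm import TINY, finetune_merger, pretrain_lm


def training_cells(n_tables: int = 120, seed0: int = 10_000) -> list[str]:
    """Cell-content corpus for LM pretraining (seeds disjoint from fixtures)."""
    cells: list[str] = []
    for k in range(n_tables):
        t = generate_resource_table(6, seed0 + k, overflow=True)
        for row in t.cells:
            cells.extend(row)
    return cells


def merge_instances(n_tables: int, seed0: int):
    """Labeled merge instances pooled over seeded overflow simulations."""
    out = []
    for k in range(n_tables):
        t = generate_resource_table(7, seed0 + k, overflow=True)
        _, _, inst = simulate_overflow(t, OverflowConfig(seed=seed0 + k))
        out.extend(inst)
    return out


@pytest.fixture(scope="session")
def tiny_lm():
    """Tiny-preset LM pretrained on a synthetic cell corpus."""
    model, losses = pretrain_lm(
        training_cells(), TINY, seed=3, steps=700, lr=1e-3, batch_size=16
    )
    return model, losses


@pytest.fixture(scope="session")
def merge_classifier(tiny_lm):
    """Merge classifier fine-tuned (2 epochs, lr 2e-4) on >= 5000 instances,
    with a disjoint held-out instance set for accuracy checks."""
    model, _ = tiny_lm
    train = merge_instances(420, seed0=20_000)
    held_out = merge_instances(40, seed0=40_000)
    assert len(train) >= 5000
    clf = finetune_merger(model, train, epochs=2, lr=2e-4, seed=5)
    return clf, held_out


@pytest.fixture(scope="session")
def overflow_fixtures():
    """50 seeded overflow fixtures (seeds disjoint from all training seeds)."""
    return [make_overflow_fixture(60_000 + k) for k in range(50)]


@pytest.fixture(scope="session")
def page_detector_setup():
    """Stacked page detector trained on a synthetic corpus, plus held-out docs."""
    train_docs = synthetic_page_corpus(seed=100, n_docs=10)
    test_docs = synthetic_page_corpus(seed=200, n_docs=6)
    detector = train_page_detector(train_docs, seed=7)
    return detector, train_docs, test_docs
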