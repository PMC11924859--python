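# Methods

## Problem and pipeline family

Key-resource tables (the STAR*Methods style: resource name / source /
identifier, with RRIDs and catalog numbers) are reconstructed from two
inputs: per-character bounding boxes extracted from a PDF page, and
table / table-structure detection boxes produced by an image-space detector.
Four variants share that front end and differ in how the grid is assembled:

* **RTE-Col** uses only column x-ranges estimated from the detected cell
  boxes. Each text-line band becomes one physical row, so a cell whose
  content wrapped onto extra lines is over-segmented; two heuristic rules
  then merge spurious rows.
* **RTE-Row** additionally bins lines into the detected row rectangles.
* **RTE-OCR** assembles the grid purely from the image modality: the crop of
  each detected cell goes through grayscale conversion, min-max contrast
  stretching, and a pluggable single-text-block OCR engine.
* **RTE-LM** runs RTE-Col and then repairs the remaining over-segmentation
  with a character-level table language model fine-tuned as a merge
  classifier.

Column ranges are far more reliable than row ranges because column gutters
are wider than row gaps; this is why the column-anchored variants exist and
why RTE-Row degrades first under detector jitter.

## Geometry

All coordinates are page points (1/72"), top-left origin, y down — the same
frame as page images, so detector boxes compose with glyph boxes after a
per-axis rescale from image pixels. Key parameters (all configurable):

| parameter | default | role |
| --- | --- | --- |
| column pad | 1 pt | slack added around estimated column ranges |
| last-column widening | 2 average char widths | guards against clipped final glyphs |
| `y_tolerance` | 0.25 × estimated line pitch | band grouping of glyph top-y values |
| `gap_factor` | 1.5 × average char width | horizontal gap that splits a line into segments |
| Rule 1 overlap | 0.70 of the text row's height | row-rectangle absorption (super/subscripts) |
| Rule 2 overlap | 0.50 of the smaller band | continuation-row absorption |
| vote threshold | strictly > 0.5 | mean column merge probability required to merge |

Column count is the lower median of per-row cell counts (the conservative
choice for even counts); overlapping column-range estimates are resolved at
interval midpoints so the ranges always partition the axis. Both overlap
rules normalize by the smaller interval, which makes superscript absorption
robust to very thin raised bands. Rule 2 is stated over vertical text-band
overlap; distinct wrapped lines have disjoint bands, so Rule 2 rarely fires
on genuine continuation rows — that residual over-segmentation is precisely
what the learned merger addresses.

## Character-level table language model

A decoder-only transformer (causal multi-head self-attention, learned
positional embeddings, pre-layer-norm blocks, GELU MLPs, token-embedding
weight tying) is trained to predict the next character of table cell
contents, each cell terminated by `<EOS>`. Cell text is short, dense, and
not natural language — catalog numbers, organism nomenclature, sequences —
which is why the model is character-level rather than subword.

Two presets: the full-scale configuration (6 layers, 6 heads, 384-d, 256
context) and a tiny preset (2 layers, 2 heads, 64-d, 64 context) used by the
tests and the acceptance script. The networks run on a small numpy
reverse-mode autodiff (`rte.nn`) written for this package; gradients were
verified against central differences during development. Training uses Adam;
pretraining defaults to lr 1e-3, and the published fine-tuning protocol (two
epochs, lr 2e-4) is kept for the merge classifier.

**Merge classification.** Row repair is cast as binary classification of
`upper <EOS> lower` strings: positives are consecutive fragments of one
split cell, negatives are neighboring complete cells. The classifier is the
pretrained trunk with one sigmoid unit reading the final-position state
(causal models summarize at the last position). When the pair exceeds the
context, the last ⌊(L−1)/2⌋ characters of the upper cell and the first of
the lower cell are kept so the `<EOS>` boundary — where the merge signal
lives — is always visible. Characters absent from the training vocabulary
are dropped from the encoding (and logged); the embedding cannot be extended
post hoc.

**Row voting.** For the current row group versus the next physical row, the
classifier scores each column pair whose cells are both non-empty; the row
merges when the mean probability strictly exceeds 0.5. Empty-cell pairs are
excluded from the vote because training positives come only from overflowing
cells, making empty pairs out-of-distribution; when every pair is excluded
the rows stay separate.

The stated full-scale parameter count in the literature (15.6 M for the
6/6/384 configuration) is not exactly reproduced by standard counting
conventions (tied embeddings give ≈15.3 M, untied ≈19.9 M); the package
reports its own count (`TableLM.n_params`) and asserts nothing about it.

## Simulated cell overflow

Training data for the merge classifier is simulated rather than annotated.
A table qualifies when some row's total character count exceeds 90 (roughly
one full text line); the allotted total row width is 80 characters for
tables whose longest row is under 100 characters, else 90. That width is
divided among columns proportionally to each column's mean cell length plus
its standard deviation — columns with higher variance get more room, the way
authors size columns — with largest-remainder rounding (deterministic, sums
exactly, each column keeps ≥ 1 character). Cells wider than their allotment
are word-wrapped greedily at spaces (words longer than the width are split
at the boundary); each logical row becomes as many physical rows as its
deepest cell, non-overflowing cells sit on the first physical row.
Consecutive fragment pairs are positives; negatives are sampled (1:1 by
default, seeded) from vertically neighboring non-overflowing same-column
cells. Fragments are re-joined with single spaces — the lossless inverse of
space-splitting — and the generator's vocabularies were chosen so no
realistic table forces a mid-word split (verified over thousands of seeds),
keeping the round trip exact.

## Synthetic data: what it does and does not emulate

The generator emulates three-column key-resource tables (antibodies,
organisms, software, chemicals) with RRID-like identifiers, catalog and CAS
numbers, bracketed fly nomenclature, optional superscript footnote marks,
multi-line overflowing cells, and page-spanning tables. The renderer is
strictly monospace with fixed column origins, one line per grid row,
optional Gaussian jitter on detection boxes, and horizontal rules around the
table; superscript marks are raised by 0.4 line heights, enough to break out
of the line-banding tolerance and trigger the spurious-line behavior the
canonicalization rules target.

It does **not** emulate proportional fonts, kerning, hyphenation,
multi-column page layouts, rotated or borderless tables, scanned-image
noise, or detector failure modes beyond box jitter. Passing the noiseless
exactness and overflow-recovery checks therefore demonstrates correctness of
the geometry, the simulation scheme, and the learned merger under the stated
layout model — not performance on arbitrary real PDFs, which additionally
depends on the external character extractor and detector.

Synthetic OCR crops are plain glyph-block bitmaps carrying their text as an
embedded payload; the fake OCR engine reads that payload (optionally with
seeded substitution noise) so the image pipeline is testable without an OCR
binary. The real-engine adapter (Tesseract, single-block mode) raises a
capability error when the binary is absent rather than returning silent
empties.

## Page detection

A two-level stacked generalizer gates the expensive detector. Level 1 is an
LSTM (single layer; hidden size 32–64 in the configurations used here) over
static word embeddings of the current line plus a two-line context window,
concatenated with four indicator bits for horizontal/vertical rules at the
current and previous line and the page number, ending in a logistic unit;
positive errors are weighted 50×. Tokenization lowercases, splits at
whitespace/punctuation, and maps digit runs to `<NUM>`. Embeddings are
pluggable word→vector tables; the self-contained default is a seeded random
50-d table, with GloVe-format files as a drop-in. Level 2 is a linear SVM
(C = 1, positive weight 5×) on the page's TF-IDF bag of words (natural term
frequency, smoothed idf, L2 norm, training-corpus vocabulary) plus the
level-1 in-table line count. Both levels threshold at 0.5 / the margin sign.

## GriTS evaluation

GriTS aligns ground truth A and prediction B by order-preserving row and
column selections maximizing a per-cell similarity f, then normalizes
F-measure style: GriTS = 2Σf/(|A|+|B|), precision Σf/|B|, recall Σf/|A| (the
harmonic-mean identity GriTS = 2PR/(P+R) holds algebraically and is asserted
to 1e-12). Content similarity is LCS(gt, pred)/len(gt) — longest common
*subsequence*, computed bit-parallel — with both-empty defined as 1 and
gt-empty/pred-nonempty as 0, since the printed ratio is undefined at
len(gt) = 0. Topology similarity is the IoU of span rectangles expressed
relative to each cell's grid position (simple cells are unit squares);
location similarity is the IoU of physical cell boxes and is reported as
unavailable, never zero, when boxes are missing.

The 2-D alignment is NP-hard in general. `best_alignment` dispatches: when
one axis admits at most 3 500 order-preserving selections (always true for
3-column resource tables, and for every grid up to ~6×6), that axis is
enumerated and the other solved exactly by a sequence-alignment DP — the
provable optimum at a fraction of full double enumeration. Larger grids fall
back to the factored iterative DP (row scores from inner column alignments,
alternating row/column passes from both a row-first and a column-first
start, to a fixed point within 10 iterations); this approximation never
exceeds and empirically rarely undershoots the optimum. A full
double-enumeration brute force is kept as the independent oracle in the
tests. Score ties between distinct optimal selections can differ by one
floating-point ulp (rounding of thirds), so equality checks use a 1e-12
absolute tolerance.

Gold/predicted table pairing (for directory-level evaluation) is greedy
best-first on vocabulary overlap |V_pred ∩ V_gold| / |V_gold| over
lowercased whitespace tokens, requiring overlap strictly above 0.40, each
table matched at most once.

## Problem sizes and numerical choices

Tests and the acceptance script use the tiny LM preset; pretraining runs 700
steps (batch 16) on a ~120-table cell corpus for the merge classifier and
1 500–2 000 steps for the 500-character memorization check; fine-tuning follows
the two-epoch / lr 2e-4 protocol on ≥ 5 000 simulated instances, with
held-out instances and fixture seeds disjoint from all training seeds. Mode
comparisons use 50 seeded overflow fixtures; page detection trains on 10
synthetic documents and evaluates on 6 held-out ones. The full-scale preset
remains available for users with a large JATS-derived cell corpus.

Degenerate inputs are defined rather than left to chance: empty tables
compare as perfectly similar only to empty tables; constant images pass
through contrast stretching unchanged; empty pages yield no text lines; a
grid with no scoreable column pairs is never merged. Ties break
deterministically (leftmost column in largest-remainder rounding, earlier
row/rectangle in overlap arguments), and every stochastic component takes an
explicit seed.

## Known limitations

* Real-PDF character extraction is delegated to an external tool behind the
  JSONL interface; no font metrics or graphics-operator parsing.
* Repeated headers of page-spanning tables are not de-duplicated; rows are
  concatenated in page order.
* The merge classifier is trained on simulated overflow from the synthetic
  generator; transfer to real tables requires re-simulating from a real cell
  corpus (the training code accepts any cell corpus).
* The location similarity requires cell boxes that only the geometric
  pipelines produce.
* Published corpus-scale figures (page-detection precision/recall on labeled
  preprints, GriTS on a curated gold set, detector accuracy) depend on
  external assets and pretrained detector weights and are out of scope here.
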