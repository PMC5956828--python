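# embedclass

Visual classification and open-set anomaly detection for tiled histology
images.

## The problem

Deep classifiers for whole-slide histopathology usually report a softmax
probability vector per image tile and average it over a slide. That works
when every slide belongs to a trained class, but in routine diagnostic
practice — the motivating setting here is surgical neuropathology — a
substantial fraction of slides show rare or never-trained entities.
Averaged probabilities are forced to distribute over the trained classes,
so novel tumors get confidently misdiagnosed, and fixing this with
post-hoc ROC cutoffs does not generalize across class mixes.

`embedclass` implements an alternative, *a priori* statistically driven
route. Per-tile feature vectors (from any embedding provider — a trained
network adapter, a precomputed table, or the shipped mock provider) are
reduced to a 2-D reference map with t-SNE. New slides are read off that
map:

1. **Gate** — keep tiles whose lesional probability exceeds 85%
   (strict `>`); abstain entirely (`INSUFFICIENT_LESIONAL`) below 15
   lesional tiles; sample at most 100.
2. **Joint embedding** — re-embed the reference tiles together with the
   slide's tiles.
3. **Discretize** — each query tile takes the modal class of its 25
   nearest reference points if that class holds ≥ 85% of them, else it is
   an `OUTLIER`; tiles whose neighborhoods lie in unoccupied map space are
   outliers regardless of purity.
4. **Verdict** — the tile contingency table is tested against a uniform
   split by a χ² goodness-of-fit statistic, Σ(Oᵢ−E)²/E with E = n/k and
   df = k−1, iteratively removing the smallest class while p < α (α = 0.01,
   fixed in advance). The procedure ends in a single **DIAGNOSIS**, a
   **DIFFERENTIAL** list of statistically indistinguishable classes, or —
   when the first iteration is significant with outliers modal —
   **UNDEFINED**.

Alongside the map-based verdict, the package computes the
softmax-averaging baseline, the conservative **combined** call (both
methods must agree, otherwise `UNDEFINED`) and a **hybrid** score
`s_c = w·frac_c + (1−w)·p̄_c` blending tile fractions with mean
probabilities. Evaluation utilities provide macro one-vs-rest mROC AUC,
accuracy/coverage sweeps over confidence cutoffs, and the Type A/B/C error
taxonomy (normal called lesion / wrong trained class / novel called
trained).

## Worked example

`examples/` holds one short script per capability. Classifying a slide of
a known tumor class (`examples/03_classify_slide.py`) prints:

```
slide slide_11_31: truth=metastasis
tiles: 80 total, 60 lesional, 60 sampled
contingency table: {'metastasis': 60}
verdict: DIAGNOSIS ['metastasis']
chi-square trail (classes, p, removed):
  {'metastasis': 60}  p=1  removed=None
probability baseline top class: metastasis (mean score 1.000)
combined (concordance) call: metastasis
```

All 60 gated tiles landed in the metastasis cluster, the table collapses
to a singleton and both routes agree. A never-trained tumor
(`examples/04_novel_detection.py`) instead prints:

```
60/60 tiles passed the lesional gate
contingency table: {'OUTLIER': 60}
map-based verdict: UNDEFINED
probability baseline would have said: meningioma
combined call: UNDEFINED
```

— the open-set case: the baseline is forced into a wrong trained class
(a Type C error) while the map-based and combined routes abstain and flag
the slide for human review.

A thin CLI wraps the same library calls:

```bash
embedclass simulate --classes 13 --slides 50 --novel 10 --seed 1 --out fixtures/
embedclass build-map --features fixtures/reference.csv --refine --out map.json
embedclass classify --slide fixtures/slide_000 --features fixtures/reference.csv \
    --map map.json --out report.json --cam cam.png
embedclass evaluate --reports reports/ --truth fixtures/truth.csv --out eval/
```

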