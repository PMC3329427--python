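# cleavekit

Cleavage-timing morphokinetics of cloned versus fertilized mouse embryos.

Somatic-cell nuclear transfer (NT) reprograms a differentiated nucleus
inside an enucleated oocyte; whether and when the embryonic cell-cycle
program is restored is visible in the *timing* of the first cleavage
divisions. `cleavekit` is a toolkit for analyzing annotated time-lapse
division tables of pre-implantation embryos — cloned (NT) against
fertilized controls produced by intra-cytoplasmic sperm injection (ICSI) —
together with amino-acid turnover profiles of their spent culture media.
It is written for embryologists and quantitative biologists who have
per-blastomere division annotations (or want realistic synthetic ones) and
need the full analysis chain in one tested package:

* **Lineage model** — parsing and validation of division-event CSVs into
  binary lineage trees (root blastomere `1`, daughters `1.1`/`1.2`, ...),
  with fates `divided / arrested / fused / censored` and M-phase aberrancy
  flags, on a common time axis of hours post activation (hpa).
* **Timing features** — per embryo: division times to the 2-, 3-, 4-, 5-,
  8-, 9- and 16-cell stages (`div1, div2.1, ..., div4.8`), mean cycle
  lengths per cleavage round (`cc1..cc4`), inter-stage durations
  (`diff2, diff3, diff4` — time spent at 3, 5–7, 9–15 cells, a sister-cell
  synchrony measure), cleavage-stage lengths and the first-cytokinesis
  duration (`ck1`).
* **Statistics** — self-contained exact Wilcoxon rank-sum and Fisher 2×2
  tests, median ± MAD group summaries, mother–daughter and sister–sister
  cycle-length correlations (Pearson r²), and a logistic regression of
  M-phase aberrancy on cycle length (IRLS with separation reporting).
* **Window predictor** — an exhaustive, exact search for the axis-aligned
  window over 1–3 timing features that maximizes the F-score
  F = 2·pr·sn/(pr+sn) of predicting blastocyst formation
  (`inside window → blastocyst`), exposed both functionally and as a
  statsmodels-style `WindowPredictor(...).fit() → results.summary()`.
* **Amino-acid turnover** — depletion/appearance rates from spent-media
  concentrations against matched embryo-free control drops,
  rate = ΔC·V/(n·t) in pmol·embryo⁻¹·h⁻¹ (positive = consumption),
  replicate matrices with SEM, and the field's heatmap clustering
  (amino acids: 1 − Spearman ρ, complete linkage; embryo-group stages:
  Euclidean, Ward).
* **Synthetic cohorts** — a calibrated branching simulator of the first
  four cleavage rounds (log-normal cycle lengths with embryo-, sister-pair-
  and inheritance-structured variance components, aberrancy and arrest
  rules, logistic outcome models) plus a spent-media generator, so the
  entire pipeline is testable without any raw-data download.

## Worked example

Simulate 200 NT and 200 ICSI embryos, extract features and compare groups:

```bash
cleavekit simulate --preset NT-default   --n 200 --seed 7 --out nt.csv
cleavekit simulate --preset ICSI-default --n 200 --seed 7 --out icsi.csv --media media.csv
python -c "import pandas as pd; pd.concat([pd.read_csv('nt.csv', comment='#'),
  pd.read_csv('icsi.csv', comment='#')]).to_csv('cohort.csv', index=False)"
cleavekit features --in cohort.csv --out feats.csv
cleavekit report --features feats.csv --media media.csv --out report.txt
```

The report begins:

```
Cleavage-stage durations (median +/- MAD, h)
     cc1     NT    17.25 +/-  0.78  (n=200)
     cc1   ICSI    18.19 +/-  0.87  (n=200)
     cc2     NT    21.23 +/-  1.37  (n=200)
     cc2   ICSI    19.07 +/-  1.02  (n=200)
     cc3     NT    16.36 +/-  1.98  (n=200)
     cc3   ICSI    12.55 +/-  0.53  (n=200)
   diff2     NT     1.49 +/-  1.03  (n=200)
   diff2   ICSI     0.89 +/-  0.61  (n=200)
   diff3     NT     4.54 +/-  1.68  (n=200)
   diff3   ICSI     1.73 +/-  0.76  (n=200)
```

Reading this: the first cell cycle (`cc1`, maternally controlled) is
slightly *shorter* in NT embryos, while the second and especially third
cycles are hours longer (here +2.17 h and +3.81 h at n = 200; Wilcoxon
p ≈ 2·10⁻²⁸ and 1·10⁻⁴⁵), and NT cleavage is less synchronous (`diff2`,
`diff3`). The slowdown coincides with embryonic genome activation at the
late two-cell stage.

The model-style predictor on the ICSI half:

```python
import pandas as pd
from cleavekit import WindowPredictor

ff = pd.read_csv("feats.csv", comment="#", index_col=0)
res = WindowPredictor.from_dataframe(
    ff[ff.group == "ICSI"], "blastocyst", ("cc1",)
).fit()
print(res.summary())
```

```
Window-rule blastocyst predictor
========================================
objective: f_score (in-sample)
n: 200   prevalence: 0.380
----------------------------------------
         cc1 in [-inf, 18.639]
----------------------------------------
F-score     0.6442
accuracy    0.6300
sensitivity 0.8816
precision   0.5076
confusion   tp=67 fp=65 tn=59 fn=9
```

i.e. fertilized embryos whose first cell cycle finishes within ~18.6 h are
predicted to reach the blastocyst stage; the in-sample accuracy of this
one-variable rule is ~63–67%. For cloned embryos the same screen yields
markedly weaker early predictors — their cleavage clock decouples from
developmental potential until after the four-cell stage.

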