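# kinoscope

Desk-side analysis for peptide-microarray kinome profiling and
kinase-inhibitor viability experiments.

A kinase-substrate chip carries ~10³ short peptides, each a recognition
motif for one or more protein kinases; incubating it with a cell lysate and
radiolabelled ATP leaves a phosphorylation fingerprint of the cell's active
kinome. `kinoscope` takes the quantified spot intensities from there to a
ranked table of active kinases and over-represented pathways, and analyzes
the follow-up inhibitor experiments (dose-response curves, censored IC50s,
drug-combination enhancement). It was built around the analysis design used
for myxoid liposarcoma cell lines and cultures — a 1024-substrate chip
spotted in triplicate with 16 negative and 16 positive controls, a
≥10⁶-hit acquisition gate, median-of-triplicate summarization, quantile
normalization, top-100 substrate selection, and comparison against
mesenchymal-stem-cell controls — but every design constant is a parameter.

Because no public array data exist for that design, the package ships a
first-class synthetic-data module: cohorts with *planted* active kinases
and pathways, so every stage of the pipeline is testable against known
ground truth.

## What it computes

* **Preprocessing** — acquisition QC (total collected hits ≥ 10⁶,
  inclusive), replicate QC (population CV of each substrate's triplicate;
  one outlier ejection at CV > 0.5), negative-control background
  subtraction, median-of-triplicate summarization, and cross-array quantile
  normalization (each array's values replaced by the across-array mean of
  order statistics at the value's rank; ties averaged; missing values
  imputed from the reference distribution and flagged).
* **Kinase activity ranking** — group-average the cohort, select the top
  *N* = 100 substrates, attribute each to its annotated kinase(s) — a
  multi-mapped substrate counts fully for each — and rank kinases by mean
  hit intensity (hit count breaks ties). The default cohort ranking
  requires ≥ 2 substrate hits of evidence per kinase; category-exclusion
  reruns (e.g. dropping `cell_cycle` kinases) recompute ranks over the
  survivors.
* **Differential specificity** — per-substrate moderated *t* on log₂
  intensities with empirical-Bayes variance shrinkage:
  s̃² = (d₀s₀² + df·s²)/(d₀ + df), t = Δ/(s̃·√(1/nₐ+1/n_b)) on df + d₀
  degrees of freedom, with (d₀, s₀²) moment-matched from the log sample
  variances and Benjamini–Hochberg FDR across substrates.
* **Pathway over-representation** — upper-tail hypergeometric test of the
  active-kinase set against user-supplied pathway membership tables
  (TSV or GMT), BH-adjusted. This is a transparent stand-in for
  knowledge-base "core analysis" scoring and is labelled as such.
* **Viability** — vehicle/blank plate normalization, bounded 4PL fits
  v(c) = lower + (upper − lower)/(1 + (c/EC₅₀)^hill), and the **absolute**
  IC50 (viability = 0.5) in closed form, censored as `NOT_REACHED` when the
  curve never crosses 0.5 in the tested range — the correct behaviour for a
  drug plateauing at 60% viability. Combinations are scored as *Bliss
  excess* (expected viability under independence, vₐ·v_b, minus observed),
  reported as "enhancement", never as synergy.

## Worked example

`examples/01_simulate_and_rank_kinases.py` simulates the default cohort
(six tumor-like arrays, six planted active kinases of 120, activity boost
3×) and ranks kinases:

```
6/6 arrays passed acquisition QC (>= 1e6 collected hits each)

Top 10 kinases (rank / mean hit intensity / hits in top-100 substrates):
 rank   intensity kinase  n_hits          description
    1 1349.935993 KIN104      12 synthetic kinase 104
    2 1322.724711 KIN057       8  synthetic kinase 57
    3 1229.157428 KIN111      11 synthetic kinase 111
    4 1223.616861 KIN004       9   synthetic kinase 4
    5 1212.231435 KIN052      11  synthetic kinase 52
    6 1129.059818 KIN095       9  synthetic kinase 95
    ...
planted active kinases: ['KIN004', 'KIN052', 'KIN057', 'KIN095', 'KIN104', 'KIN111']
all planted recovered in top 10: True
```

The intensity column is the mean normalized intensity of the kinase's
substrates among the top-100 spots; `n_hits` is how many of those
substrates it owns. All six planted kinases surface in the top ten, and
`examples/03_pathway_enrichment.py` shows the planted pathway at rank 1
with p ≈ 6·10⁻⁸. `examples/04_dose_response_ic50.py` and
`examples/05_combination_bliss.py` cover the viability side, including the
worked combination numbers (mono 0.80 × fixed 0.50 → Bliss expectation
0.40; observed 0.05 → excess 0.35, flagged as enhancement).

A thin CLI wraps the same functions:

```
kinoscope simulate --preset paper --seed 1 --out run/
kinoscope run --seed 1 --out run/        # full pipeline + manifest
kinoscope viability --plate run/viability/drug_a.csv --out fit.tsv
```

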