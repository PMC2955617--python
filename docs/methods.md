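# Methods

## Scope and data model

The pipeline starts at quantified spot intensities (TSV, or GenePix GPR
with `Name` → substrate and a configurable intensity column, `F532 Median`
by default) and a chip layout listing every physical spot: substrate
identity, 0-based replicate index, 0-based (block, row, col) grid
coordinates, and control status. The packaged default layout mirrors a
1024-substrate chip spotted in triplicate with 16 negative and 16 positive
controls. Whether the vendor spotted controls in replicate is not
documented anywhere we could verify; the default layout spots each control
once, which is a package convention, not a claim about the physical chip.

Substrate→kinase annotation is many-to-many: peptide motifs are shared
across kinases (notably within kinase families), so one bright spot can be
evidence for several kinases at once. Unannotated substrates are retained
through preprocessing and top-N selection — dropping them early would bias
the top-N composition — they simply contribute to no kinase.

## Preprocessing

Stages run in the order acquisition QC → replicate QC → background
correction → median summarization → quantile normalization. Normalizing
summarized profiles (one value per substrate) rather than raw spots is the
default because it is robust to spot dropout; the spot-level order is
available via `normalize_before_summarize=True`.

* **Acquisition QC**: an array passes iff its total collected hits
  (treated throughout as summed spot intensity) reach the threshold,
  default 10⁶, inclusive. Failing arrays are excluded with a logged reason.
* **Replicate QC**: the published procedure ("quality of the triplicates
  was assessed") is unspecified, so this package's concretization is: per
  substrate, the population CV of unflagged replicates; if CV > 0.5, eject
  the single replicate farthest from the replicate median and recompute
  once — never a second ejection. Substrates with fewer than 2 surviving
  replicates are flagged `dropout` (a flag, not an error).
* **Background**: subtract the mean negative-control intensity from every
  substrate spot, clipping at zero. Chips without negative controls must
  disable this stage explicitly.
* **Summarization**: median of unflagged replicates; with exactly two
  survivors the median equals their mean.
* **Quantile normalization**: the published "quartile normalization
  (Affyio)" is read as quantile normalization — quartile-only
  normalization is not a defined procedure in that toolchain. Each array's
  values are replaced by the across-array mean of order statistics at the
  value's rank; tied values receive the mean of their tied reference
  values, so untied within-array order is preserved exactly. A value
  missing in one array is imputed from the reference quantile function at
  the substrate's mean empirical quantile across the arrays where it is
  present, and flagged `imputed`; this is a package decision — a missing
  entry has no rank of its own, so some cross-array borrowing is
  unavoidable. The implementation agrees with a brute-force
  sort/row-mean/map-back oracle to < 10⁻¹² on complete matrices.

## Kinase activity ranking

Default flow: arithmetic group average over samples where the substrate
passed QC → top *N* = 100 substrates by intensity (ties at the cut broken
by lexicographic substrate id, so the cut is deterministic) → per-kinase
aggregation: `n_hits` = its annotated substrates in the top list,
`mean_intensity` = their mean. A substrate annotated to several kinases
contributes fully to each, which is how two kinases can share one printed
intensity. Ranking is by mean intensity descending, ties by hit count then
id — the order the published activity table is printed in.

`score_kinases` reports every kinase with ≥ 1 hit, matching the published
table shape (which contains single-hit rows). The cohort-level default
(`infer_kinase_activity`) additionally applies `min_hits = 2`. Rationale:
a single spot's intensity is a noise-dominated estimate of kinase
activity, and under many-to-many annotation a lone shared substrate
attributes one kinase's signal to another; requiring at least two
concordant substrate hits is the standard minimum-evidence guard in
upstream kinase inference (kinase-substrate enrichment tools impose
substrate-count minimums for the same reason), and the published "top
activated kinases" shortlists likewise contain no single-hit entry. With
single-hit calls admitted, planted-kinase recovery on the default
synthetic cohort collapses (≈ 17/100 seeds instead of ≈ 100/100), driven
entirely by single-substrate attributions — a property of the estimator,
not of the simulation.

Hit counts refer to the top-100 list only (the published wording ties hits
to the top 100 substrates), not to the whole chip. A per-sample mode
(top-N per sample, cross-sample hit frequency) is provided because
averaging-then-selecting versus selecting-then-counting is genuinely
ambiguous in the source design; the averaged flow is the default.

Category-exclusion reruns (e.g. `cell_cycle`, covering ~27% of kinases in
the default annotation, which may be artificially active in cultured
cells) drop tagged kinases and recompute ranks over survivors; unknown
tags are an error listing the known ones.

## Differential contrast

Per substrate, a two-sample contrast on log₂(x + 1) intensities (the +1
offset tolerates background-corrected zeros). The pooled variance s² with
df = nₐ + n_b − 2 is shrunk toward a chip-wide prior:

    s̃² = (d₀·s₀² + df·s²) / (d₀ + df),
    t = (x̄ₐ − x̄_b) / (s̃·√(1/nₐ + 1/n_b)),  on df + d₀ degrees of freedom.

(d₀, s₀²) are estimated by moment matching on log sample variances under
the scaled-F model s² ~ s₀²·F(df, d₀): the excess of var(log s²) over
trigamma(df/2) determines d₀ through the inverse trigamma function (Newton
iteration); the mean then determines s₀² with the log-chi-square bias
correction. When the observed dispersion does not exceed what sampling
alone explains, d₀ is reported as an infinity sentinel and s₀² as the
arithmetic mean of the variances; every substrate's variance is then
pinned at s₀² and the reference distribution is normal. d₀ = 0 recovers
the ordinary pooled t exactly (verified to 10⁻¹⁰ against an independently
coded oracle); the null type-I error at α = 0.05 on 10⁴ substrates with
4-vs-2 samples lands in [0.04, 0.06]. BH step-up q-values control FDR and
are permutation-stable.

## Pathway over-representation

The proprietary pathway "core analysis" of the original toolchain cannot
be replicated; a transparent upper-tail hypergeometric test over a
user-supplied kinase→pathway table is substituted and labelled as such in
every report. For a pathway with K members in a universe of M kinases and
an active set of N, p = P(X ≥ overlap), X ~ Hypergeometric(M, K, N);
results are BH-adjusted and sorted by p, then larger overlap, then id. The
active set defaults to the top-10 ranked kinases. An empty active set
yields p = 1 everywhere by convention (with a warning). The implementation
matches exact rational-arithmetic enumeration for every feasible
configuration with M ≤ 15.

## Viability analysis

Raw plates are long-format absorbance tables with blank, vehicle and
treated roles; viability = (A − mean blank)/(mean vehicle − mean blank),
replicates preserved. Wells darker than blank produce negative viabilities
which are *retained* (with a warning): clipping would bias the lower
asymptote of the subsequent fit.

The curve model is the decreasing 4PL
v(c) = lower + (upper − lower)/(1 + (c/EC₅₀)^hill); no model was named in
the source design, and the 4PL is the field default. Fits are bounded
least squares (lower ∈ [0,1], upper ∈ [0.5,1.5], EC₅₀ within
[min dose/10, max dose·10] on the log scale, hill ∈ (0,10]) from three
deterministic starts; the best residual sum of squares wins, and optimizer
failure returns best-effort parameters with `converged=False`.

The IC50 is the **absolute** one — where fitted viability crosses 0.5 —
solved in closed form and censored as `NOT_REACHED` when the crossing does
not occur inside the tested dose range (in particular whenever the lower
asymptote ≥ 0.5). The absolute definition is the only one under which "a
maximum viability decrease of 40%, no IC50 calculable" is coherent, which
is exactly the monotherapy behaviour this module must represent.

Combination plates (drug A titrated on a fixed dose of drug B) are scored
per shared dose as Bliss excess = vₐ·v_b − v_combo; the enhancement flag
requires excess > 0.1 at ≥ 2 doses. The statistic is always labelled
"enhancement (Bliss excess)": when a monotherapy IC50 is censored, a
formal synergy analysis (e.g. combination index) is impossible, so the
tool never claims one. The administration schedule (drug B 30 minutes
before drug A) is recorded as metadata and does not alter computation.

## Synthetic data: what it emulates, what it does not

Arrays: spot intensity = lognormal(μ, σ) background, multiplied by `boost`
for substrates annotated to any planted active kinase, by a shared
substrate draw jittered per replicate at CV `replicate_cv`, with spots
removed at `dropout_rate`. Positive/negative controls sit at the 99th/1st
percentile of background so QC behaviour is unambiguous (their levels are
otherwise undocumented). Defaults: μ = 6.0, σ = 0.5 (natural log; ~12×
spot-to-spot spread per array, about an order of magnitude of dynamic
range), boost = 3, CV = 0.1, dropout = 0.01. Boost and CV are the
benchmark conditions the recovery properties are stated at; μ, σ and
dropout are fixtures chosen once as plausible for radiolabel arrays — no
published noise magnitudes exist for this chip, so they are not estimates
of it. μ = 6 makes a full chip collect ~1.5·10⁶ total hits, comfortably
clearing the acquisition gate. The default cohort mirrors the study shape:
six tumor-like samples under one planted set of six kinases (covered by a
planted pathway) and two control-like samples under a disjoint planted
set.

Deliberately not modelled: persistent substrate-affinity differences
(every substrate shares one background distribution across samples),
spatial artifacts, scratches and gradients, image-level effects. The
consequence worth stating: on real chips, absolute top-N selection reads
out affinity × activity, not activity alone — which is exactly why the
control contrast (moderated t vs. MSC-like arrays) exists. Passing
recovery tests on this generator therefore demonstrate correctness of the
pipeline's statistics under its stated model, not robustness to
affinity confounding.

Viability plates simulate absorbances as blank + span·(v + noise) with v
from a 4PL; vehicle wells sit at v = 1 and blanks at the blank level, so
normalization is exercised end to end. Quadruplicate wells on the two
packaged six-dose grids (50–5000 nM; 10–500 µM) mirror the study design;
`noise_sd` = 0.02 viability units is the benchmark noise condition.

## Numerical choices and edge cases

* Selection and ranking tie-breaks are lexicographic ids everywhere, so
  every ordering is deterministic and permutation-stable.
* `bh_fdr` validates p ∈ [0,1], uses a stable sort, and enforces step-up
  monotonicity.
* CVs use the population (ddof = 0) standard deviation; substrates with a
  zero mean or fewer than two replicates get CV 0 (they are handled by the
  dropout rule instead).
* The trigamma inverse uses the standard asymptotic start 1/y + 1/2 with
  Newton updates; targets above 10⁷ short-circuit to 1/√y.
* All generator randomness flows through `numpy.random.default_rng` seeds
  carried in the truth objects; identical truth ⇒ bit-identical tables.
* The pipeline manifest hashes the config (excluding the output
  directory), so identical config + seed reproduce byte-identical outputs.

## Problem sizes used in the checks

The recovery properties are computed at the study-shaped scale: 100
simulated cohorts of six 1024-substrate arrays for kinase/pathway
recovery; 10⁴ substrates for null calibration; 5·10³ variances for
hyperparameter recovery; 200 simulated plates for noisy EC₅₀ recovery; 100
random matrices (≤ 50×8) for the normalization oracle; every feasible
configuration with universe ≤ 15 for the enrichment oracle. These sizes
keep the full check suite in the tens of seconds while leaving the
Monte-Carlo margins far from the acceptance thresholds (observed rates sit
at 99–100% against 95%/99% requirements).

## Known limitations

* No spatial or print-tip normalization; the pipeline begins at quantified
  spots.
* The hypergeometric substitution means pathway *identities* from
  knowledge-base scoring are out of reach by design; only the
  over-representation machinery is reproduced.
* The moderated-t stage has no external numeric anchor (the source design
  reports no effect sizes or q-values for its control contrast), so its
  validation is purely property-based: limits, calibration, and
  hyperparameter recovery.
* `fit_4pl` assumes monotone-decreasing viability in dose; biphasic
  responses will fit poorly and should be caught via `rss`/`converged`.
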