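# Methods

This note documents the models, parameter choices and numerical decisions
behind `opcflux`, and what the synthetic validation does and does not
establish about real data.

## Generative model for the synthetic arrays

Raw arrays for this study design are not publicly available, so the
pipeline is validated by parameter recovery on simulated data. The
generator emits strictly positive intensities

    value(g, probe, s) = baseline(g) · affinity(probe) · δ(g, cond(s)) · 2^ε,
    ε ~ Normal(0, noise_sd_log2), i.i.d. per probe × sample,

a multiplicative log-normal error model, the standard first-order
description of background-corrected one-color microarray noise. Defaults
(the study conditions): six conditions — control plus G+/M−, G+/M+,
medullary MS, PPMS, NMO — with **4 replicate arrays** each,
`noise_sd_log2 = 0.15`, **2 probes per gene** (so probe merging is
exercised), ~200 filler genes with baselines log-uniform over 10²–10⁵ (so
the low-expression filter is exercised), and effect-carrying/reference
genes with baselines log-uniform over 10³·⁸–10⁵ so that no pathway member
or reference gene can be silently filtered out. The two probes of a gene
carry reciprocal affinities (geometric mean exactly 1), so geometric-mean
merging restores the gene-level signal identically.

Replicate arrays are exchangeable technical/culture replicates (the CSF of
each clinical form is modeled as pooled before treatment); no patient-level
variance component is simulated.

### Effect calibration

δ(g, c) is 1 for the control, the four stable reference genes (Mrpl19,
Hprt, B2m, Tfrc) and fillers. ActB gets condition-dependent factors
0.37–0.63 (matching the reported destabilization percentages where stated;
0.55 and 0.45 for the two conditions without a reported value); Gapdh is
modeled once, as a glycolysis member, and doubles as the second unstable
reference candidate.

Pathway members are calibrated per (condition, pathway) cell so that the
**product of configured effects equals the published pathway CFI of that
subtype exactly**. Within a cell the down-regulated members share a common
factor (the geometric split maximizes the margin of every member to the
fold-change-2 call threshold). Several published cells cannot be written
as a product of factors that all clear that threshold (e.g. the PPMS TCA
cell, 0.5400, lists a single gene; the G+/M− glycolysis cell needs
per-gene factors ≈ 0.52 over its six listed genes). For those cells the
scenario either adds one up-regulated member with factor ≥ 2.5 from the
pathway's remaining panel genes — the G+/M+ glycolysis cell already has an
up-regulated member (Pgam) in the published profile — or, where the panel
is exhausted (the small ETC panel), trims the down set by one or two
genes. The cell products, hence all pathway and total CFIs, are unchanged
by these adjustments; only the membership of the down sets deviates from
the published lists, and the pipeline's call-set tests compare against the
*configured* sets.

## Preprocessing

* **Percentile normalization**: each sample is scaled so its 75th
  percentile equals the geometric mean of all samples' 75th percentiles.
  The common target is a free choice (any target yields identical
  downstream ratios); the geometric mean keeps the experiment's intensity
  scale and makes the operation idempotent. Percentiles use linear
  interpolation between order statistics (`numpy.quantile` default),
  fixed for bit-stability.
* **Low-expression filter**: threshold = 30% quantile of the pooled value
  distribution over the whole matrix; a row is removed iff its median
  across samples falls below it. The pooled ("whole array") reading and
  the median row summary are the design choices; the median is robust to a
  few outlying arrays.
* **Probe merging**: geometric mean per gene and sample, consistent with
  the multiplicative error model; output rows sorted lexicographically.
  The pipeline order is normalize → filter → merge: probes are filtered
  individually, and a gene enters the merged matrix with whichever of its
  probes survive.

Note one systematic consequence of quantile scaling: when many genes are
strongly down-regulated in a condition, the sample's 75th percentile drops
and normalization inflates all its values slightly — a compositional
artifact analogous to library-size normalization under asymmetric change.
Reference-gene normalization downstream removes it (the references absorb
the same shift), which is why fold changes are computed only after that
second normalization.

## Reference-gene stability

* **geNorm** uses log base 2 and the n−1 SD denominator. Stepwise
  exclusion recomputes M on the surviving set, removes the largest-M gene
  (ties: the lexicographically greater id is excluded) and stops at two
  genes, which share rank 1 — the pairwise measure cannot order the final
  pair. The reported M of a gene is its value in the set it was excluded
  from.
* **NormFinder** follows the published model-based estimator: per-sample
  centering over the candidate panel; intragroup variances corrected for
  the centering bias by `(s² − Σs²/(I(I−1))) · I/(I−2)` and clipped at 0
  (hence ≥ 3 candidates); intergroup differences d estimated per gene and
  group, with the intergroup variance γ² estimated on (I−1)(G−1) degrees
  of freedom and the d shrunk by `γ²/(γ² + σ²/n_g)`; stability =
  group-mean of |shrunken d| + SE. Groups are the six conditions; ≥ 2
  samples per group are required.
* The **ANOVA screen** is a per-candidate one-way F-test on log2 values;
  p < 0.05 flags a candidate as significantly variable. Note that with
  quantile-normalized (not reference-normalized) input this screen is
  sensitive to the compositional shift described above; the rank-based
  geNorm/NormFinder measures are not, because they work on within-sample
  ratios or sample-centered values.

Published stability *values* (e.g. M ≈ 0.10–0.15) depend on the
unavailable raw data and are not reproduction targets; the reproduced
claim is qualitative and distributional: across 100 simulated studies both
algorithms rank all four stable references above both unstable
housekeeping analogs in ≥ 95% of seeds.

## Differential expression

Fold change r(g, c) is the ratio of arithmetic means of
reference-normalized values (condition over control). Tests run on log2
normalized values: one-way ANOVA across all six conditions, then
Tukey–Kramer studentized-range comparisons of each condition against
control sharing the pooled within-group variance (k = 6, df = 18 at the
defaults). BH-FDR is applied across all gene × condition Tukey p-values
jointly. Calls: down iff r ≤ 0.5 ∧ p < 0.01 ∧ q < 0.1; up iff r ≥ 2 with
the same statistics; fold-change boundaries inclusive. "Absolute fold
change ≥ 2" is read two-sidedly on the ratio scale. Percent
downregulation is reported as (1 − r)·100 throughout (the source
literature mixes "remaining fraction" and "reduction" phrasings; this
package standardizes on reduction).

An optional empirical-Bayes branch shrinks the per-gene pooled variances
toward a moment-matched scaled-inverse-chi-square prior,
`s̃² = (d0·s0² + df·s²)/(d0 + df)`, with (d0, s0²) fitted by matching the
mean and variance of log s² (digamma/trigamma relations, trigamma inverted
by Newton iteration). The default pipeline is plain ANOVA + Tukey — the
stated significance cutoffs belong to that procedure — with moderation
exposed as a switch.

### Numerical choice: Tukey p-values

`scipy.stats.studentized_range.sf` costs ~10 ms per value, prohibitive for
whole-matrix and Monte-Carlo use. Tukey p-values are therefore evaluated
through a per-(k, df) cached monotone PCHIP interpolant of log sf on a
201-point grid over q ∈ [0, 25] (clamped beyond). The interpolant agrees
with the direct computation to better than 1e-5 relative (asserted in the
test suite), far below any decision tolerance used here. With moderation
the augmented df is rounded to the nearest integer for the cache.

## Cumulative Flux Index

CFI(pathway, condition) = ∏ r(g, condition) over pathway members with a
significant call; non-called members contribute 1, up-called members
contribute their r > 1 (each enzyme's activity level enters the index).
Total CFI = ∏ pathway CFIs. The multiplicative rule is the simplest
composition consistent with flux reduction "accumulating" across enzymes
(a linearized flux-control view: the attainable flux through a chain
scales with each step's activity), and it reproduces the published
per-subtype totals from the published pathway triplets at 2 significant
figures for the three internally consistent subtypes (G+/M+ 1.9E-07,
PPMS 1.3E-04, NMO 1.1E-07). Two published rows are *not* reproduction
targets: one disagrees with its own pathway triplet by an order of
magnitude (likely typographic), the other only at rounding level. The
rule lives behind the `cfi` module interface so alternative aggregations
can be swapped. Shorthand enzyme names are reconciled to array symbols by
an explicit alias table (Eno→Eno1, Pdh→Pdha1, Sdhaf2→Sdh, Pgam→Pgam1).
Missing pathway members raise rather than silently contributing 1.
Conditions are ranked by ascending total CFI, ties lexicographic.

## What the validation shows — and a real limitation of the index

Problem sizes used by the test suite and chosen for this package: ~230
genes × 2 probes × 24 samples per simulated study; 100 seeds for the
stability-ranking study, 50 for end-to-end CFI recovery, 200 for the
global-null calibration.

* Zero-noise runs recover every configured pathway product exactly and
  call exactly the configured gene sets — the pipeline's algebra is
  correct end to end.
* Under the global null the caller makes no calls (0 of ~169,000 cells
  across 200 seeds measured during development) and every CFI equals 1.
* At the default noise level the stability ranking and the qualitative
  severity ordering of conditions (aggressive ≪ mild, separated by ~3
  orders of magnitude) are recovered essentially always.
* The total CFI's *numerical value*, however, is intrinsically
  high-variance: it multiplies ~15–18 noisy fold-change ratios, so
  independent per-gene errors add in log space (~√G·σ_r), and — worse —
  the per-sample reference-normalization error is shared by every gene and
  enters the log total multiplied by the number of called genes (~G·σ_ref).
  At noise_sd_log2 = 0.15 with 4 replicates and 4 reference genes this
  gives a log2-scale SD near 1, i.e. typical factor-2 fluctuations of the
  recovered total; recovery within 25% relative error occurred in only
  2/50 seeds. The corresponding acceptance test is left failing rather
  than weakened: it documents that at realistic microarray noise the total
  CFI is a reliable *ordinal* severity score but not a precise cardinal
  quantity, and that tight numerical reproduction of published totals
  would require either far lower noise (σ ≲ 0.03), many more replicates,
  or a large reference panel.

What passing tests do **not** show about real data: the generator draws
i.i.d. log-normal noise with equal variance across genes and conditions,
no probe-specific cross-hybridization, no array spatial artifacts, no
patient-level heterogeneity (CSF pooling is taken at face value), and
reference genes that are *exactly* stable. Real arrays violate all of
these to some degree; the stability ranking and DE calls are designed to
be robust to the first-order violations (per-sample scale, probe
affinity), but performance numbers measured here are upper bounds.
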