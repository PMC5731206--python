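# Methods

## The mixture model behind the analysis

Bulk testis expression is treated as a compositional mixture of cell-type
transcriptomes. Each cell type $c \in \{\text{germ}, \text{Sertoli},
\text{Leydig}, \text{other somatic}\}$ has a profile $p_{tc}$ — the fraction
of that cell type's mRNA contributed by transcript $t$ (profiles sum to 1
over transcripts). A bulk sample under condition $k$ with mRNA mass
fractions $w_c(k)$ (summing to 1) has expected relative abundance

$$x_t(k) \propto \sum_c w_c(k)\, p_{tc},$$

renormalized to a fixed per-sample total. This renormalization is the
FPKM-style constraint that creates *apparent* enrichment: removing the
germ-cell mass fraction $f_g$ multiplies every purely somatic transcript by
exactly $1/(1-f_g)$. The identity is exact at zero noise and is asserted by
the tests; it is also what ties the simulator to reality — the default
$f_g = 1 - 1/6.49 \approx 0.846$ reproduces the ≈ 6.5-fold somatic-marker
enrichment observed after germ-cell ablation in the adult testis.

### Assumptions

* Ablations are complete by default (germ and Sertoli removal fractions of
  1.0 are exposed as parameters for robustness experiments).
* Per-cell expression of a transcript does not change when *other* cell
  types are removed — except for the explicit confounder class below.
* Replicate (between-animal) variation is multiplicative lognormal with a
  common coefficient of variation; abundances stay non-negative and no
  pseudocounts are ever introduced. Undefined ratios (zero denominators)
  are flagged, not imputed.

## Specificity criteria

A transcript is Sertoli-specific when (i) its germ-ablation fold change is
**strictly** greater than the floor (relaxed 2, strict 5 — an observed
increase is required, so transcripts with a zero control mean are
unclassifiable), (ii) its residual fraction after Sertoli ablation is at or
below the ceiling (relaxed 0.30, strict 0.10 — the ceiling is inclusive,
"a 70 % decrease"), and (iii) the Sertoli-ablation reduction is significant
at BH-FDR 0.05, with at least one of the two contrasts significant
(`significance_mode="busulfan_or_dtx"`, the default; a `dtx_only` mode is
provided). Germ-cell specificity requires a residual after germ ablation
**strictly** below 0.10 ("> 90 % reduction") with a significant reduction.
Boundary behavior is deliberate and configurable; tightening any threshold
can only shrink the call set (tested property).

Both classifiers are, by construction and by test, identical to an
exhaustive row-by-row filter; the implementation is vectorized only for
speed.

## Statistics

* Two-group contrasts use Welch's unequal-variance *t* by default (replicate
  numbers can differ between groups); a pooled *t* and a one-way ANOVA are
  provided. Transcripts that are all-zero in both groups are kept with
  p = 1 so the transcript universe stays aligned across contrasts.
  Degenerate rows (zero variance in both groups) get p = 1 when the means
  agree and p = 0 otherwise.
* Multiple testing uses Benjamini–Hochberg step-up adjustment, one family
  per contrast across all transcripts with a defined p-value (delegated to
  statsmodels; tested against a brute-force implementation of the step-up
  definition).
* The knockout analysis fits a per-transcript 2×2 factorial ANOVA with
  interaction. With balanced data (4/group by default) the classical sums
  of squares coincide and are computed in closed form, vectorized across
  transcripts (validated against an OLS `anova_lm` oracle to 1e-8);
  unbalanced input falls back to per-transcript Type-II OLS with a logged
  warning. BH families are per effect (FSHR, AR, interaction) across
  transcripts. Where the interaction is significant (q ≤ FDR), Tukey
  honest-significant-difference p-values over the four genotype means
  (studentized-range distribution, pooled residual mean square) replace the
  main-effect p-values for the knockout-vs-control comparisons, and a
  compact letter display is reported; otherwise main-effect p-values come
  directly from the ANOVA.
* **Analysis scale.** The default is the normalized linear scale, matching
  the per-Sertoli-cell normalization contract (signal divided by the
  enrichment factor). Additivity is scale-dependent, so a `transform="log2"`
  option is provided: multiplicative knockout effects are additive — and
  the simulator's lognormal noise exactly Gaussian — on the log scale. The
  calibration and power checks therefore run on the log2 scale, where the
  interaction F-test holds its nominal size; on the linear scale the same
  test is mildly anticonservative under lognormal noise at n = 4
  (measured type-I ≈ 0.06 at α = 0.05).

## Synthetic data: what it emulates, and what it does not

`generate_truth` draws a transcript universe with exclusive classes
(defaults: 30 % germ-exclusive, 10 % Sertoli-exclusive, 5 % Leydig, 5 %
other-somatic) and shared transcripts for the remainder. Exclusive
transcripts get a lognormal abundance (meanlog log 30, sdlog 1.2, arbitrary
per-cell units) in their home cell type only. Shared transcripts vary
moderately between cell types (uniform ×0.6–×1.4 around a common level),
the housekeeping-like regime; strongly cell-biased multi-cell-type
transcripts — the acknowledged misclassification risk — are modeled
explicitly by the optional `sertoli_dependent_other` confounder class,
whose per-cell expression in surviving cell types drops to 5 % after
Sertoli ablation.

Control composition: germ 0.846 (see above), with the somatic remainder
split 45 % Sertoli / 25 % Leydig / 30 % other. Replicate noise CV defaults
to 0.2 (between-animal variance in such designs is rarely reported; 0.2 is
a realistic bulk-RNA figure and is a parameter, not a finding). Default
study sizes mirror the designs analyzed: 5 replicates/condition for the
three-condition ablation study, 4/genotype for the knockout arrays; the
test suite and acceptance script use 1,000–2,000 transcripts, which is
ample for the rates they estimate while keeping runs to seconds.

The knockout simulator scales the Sertoli mixture weight by each genotype's
Sertoli-cell density ratio (the enrichment factor) from a morphometry
preset (EF 1.4 / 1.42 / 2.0 for FSHRKO / SCARKO / double knockout —
volumes fall faster than Sertoli counts in these models) and multiplies
Sertoli per-cell expression by the transcript's effect multipliers
(`fshr_effect`, `ar_effect`, and `interaction_multiplier` in the double
knockout). Unlike the ablation simulator it does **not** renormalize
samples to a fixed total: the array contract is absolute per-testis signal,
which is exactly what dividing by the enrichment factor undoes. Effect
defaults: half of Sertoli-exclusive transcripts down-regulated 2–5-fold per
knockout, 2 % up-regulated 1.5–2.5-fold (up-regulation is rare in these
models), 25 % of affected transcripts with a synergistic interaction
(multiplier 0.2–0.6).

What passing tests on this generator do *not* show about real data: the
generator has no isoform structure, no count-level (shot) noise, no
correlated transcript modules, no partial ablation or germ-cell
regeneration, and no Sertoli-dependent reprogramming of Leydig cell state
beyond the simple confounder class. Results on it validate the *logic and
calibration* of the pipeline, not the biological completeness of any
particular call set.

## Numerical choices and degenerate inputs

* Fold changes and log-ratios are undefined (NaN) when denominators are
  zero; classifications treat undefined as "cannot qualify".
* Tables are TSV; floats round-trip at full precision (`%.17g` out,
  round-trip parsing in).
* Enrichment "average" over a marker panel is the arithmetic mean (a
  geometric option exists); panel symbols match case-insensitively.
* Gene-symbol joins trim and case-fold, with no alias/ortholog resolution —
  a documented source of undercounting in cross-study comparisons.
* Zero residual variance in the ANOVA yields undefined p-values (logged),
  never fabricated significance.
* Seeds: every stochastic routine takes an explicit integer seed;
  identical seeds give bit-identical truths and matrices.

## Known limitations

Leydig/peritubular-specific calling is out of scope (no enumerated
criteria); the classifier cannot distinguish a true Sertoli transcript from
one in another cell type that strictly requires Sertoli cells (use the
confounder class to quantify this risk under assumptions); FPKM-scale
input is taken as given — no read-level processing or count-based
dispersion modeling is attempted.
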