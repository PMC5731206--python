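# sertoliseq

Cell-type-specific transcript calling in the mouse testis from **sequential
cell-ablation** expression data, plus downstream analysis of the hormonal
(FSH/androgen) control of the Sertoli-cell transcriptome.

## The problem

Bulk testis RNA is a mixture of germ-cell and somatic (Sertoli, Leydig,
peritubular/other) transcriptomes, with germ cells contributing the large
majority of the mRNA mass. Which transcripts belong to which cell type can
be inferred without sorting cells: ablate one cell population and watch each
transcript's abundance respond.

* **Germ-cell ablation** (busulfan) removes germ-cell mRNA. Because
  RNA-seq abundances (FPKM) are *relative*, every surviving somatic
  transcript shows an apparent increase — if germ cells contributed a
  fraction $f_g$ of the mRNA, somatic transcripts rise by the
  renormalization factor $1/(1-f_g)$ (≈ 6.5-fold for the adult testis).
  Transcripts that instead collapse (> 90 % loss) are germ-cell-specific.
* **Sertoli-cell ablation** (diphtheria toxin in an iDTR model, applied to
  the germ-free testis) then removes Sertoli mRNA. A transcript that rose
  after germ-cell ablation and then lost ≥ 70 % of its level is called
  **Sertoli-cell-specific** (relaxed criteria: fold change > 2, residual
  ≤ 0.30, significant reduction at BH-FDR 0.05; strict: > 5-fold, ≤ 0.10).

For the hormone analysis, testes from a 2×2 knockout design — control,
FSHR knockout (FSHRKO), Sertoli-cell androgen-receptor knockout (SCARKO)
and the double knockout — are first normalized by the **Sertoli mRNA
enrichment factor**

$$\mathrm{EF}(X) = \frac{\text{Sertoli cells}_X/\text{testis volume}_X}
                        {\text{Sertoli cells}_{ctrl}/\text{testis volume}_{ctrl}},$$

so signal is expressed per Sertoli cell, and then analyzed
transcript-by-transcript with a two-factor ANOVA with interaction
(BH-adjusted per effect family; Tukey HSD post-hoc where the interaction is
significant). A significant interaction means the double knockout departs
from additivity (synergy).

Every stage is verifiable against a ground-truthed synthetic testis-mixture
generator: bulk expression as a composition-weighted sum of cell-type
profiles under ablation, and knockout arrays with per-transcript effect
multipliers and genotype-specific Sertoli numbers.

## Worked example

```python
import sertoliseq as sq

truth = sq.generate_truth(1000, seed=1)                      # ground truth
em = sq.simulate_ablation_study(truth, n_replicates=5, seed=2)

bus = sq.compute_group_contrast(em, "control", "busulfan")   # germ ablation
dtx = sq.compute_group_contrast(em, "busulfan", "busulfan_dtx")

est = sq.estimate_enrichment_from_markers(bus, truth.marker_panel(25))
print(f"somatic enrichment {est.mean_fc:.2f}-fold "
      f"(range {est.min_fc:.2f}-{est.max_fc:.2f}, n={est.n_used})")

calls = sq.classify_sertoli_specific(bus, dtx, sq.make_criteria("relaxed"))
ev = sq.evaluate_calls(calls, truth)
print(f"{ev.tp + ev.fp} Sertoli-specific calls, "
      f"sensitivity {ev.sensitivity:.2f}, specificity {ev.specificity:.2f}")
```

prints

```
somatic enrichment 6.57-fold (range 4.81-8.59, n=25)
100 Sertoli-specific calls, sensitivity 1.00, specificity 1.00
```

The 6.57-fold mean is the apparent somatic enrichment created by removing
the germ-cell mRNA mass (the generator's default germ fraction puts the
ideal value at 6.49); the classifier recovers all 100 planted
Sertoli-exclusive transcripts with no false positives at this noise level
(lognormal CV 0.2, 5 replicates/group).

The same pipeline is available from the shell:

```bash
sertoliseq simulate ablation --n-transcripts 1000 --seed 1 --out-dir sim/
sertoliseq contrast run --matrix sim/matrix.tsv --design sim/design.tsv \
    --ref control --alt busulfan --out bus.tsv
sertoliseq contrast run --matrix sim/matrix.tsv --design sim/design.tsv \
    --ref busulfan --alt busulfan_dtx --out dtx.tsv
sertoliseq classify sertoli --bus bus.tsv --dtx dtx.tsv --preset relaxed --out calls.tsv
sertoliseq hormone --matrix ko/matrix.tsv --design ko/design.tsv \
    --morphometry ko/morphometry.tsv --out anova.tsv
```

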