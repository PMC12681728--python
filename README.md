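# g6pdscreen

Flagging probable carriers of the X-linked G6PD p.Val68Met variant
(rs1050828-T) from two routine laboratory values, for biostatisticians
and clinical-informatics teams who want to screen EHR populations
without genotype or enzymatic assays.

## The idea

G6PD deficiency shortens red-cell lifespan, so HbA1c — which accumulates
over a red cell's life — under-reports true glycemia in carriers. Two
cheap labs capture that signature:

* the **glucose gap** GG = glucose − eAG, with
  eAG = 28.7 × HbA1c − 46.7 (mg/dL): carriers sit at less negative gaps;
* a **low red cell distribution width** (RDW ≤ 12).

The decision rule calls **possible** deficiency when *either* criterion
holds (RDW ≤ 12 or GG ≥ −15 mg/dL, screening-oriented) and **likely**
deficiency when *both* hold (confirmation-oriented); likely ⊆ possible.
Around the rule the package provides:

* cohort construction (draw eligibility 70–200 mg/dL when fasting is not
  assured, lowest-glucose index draw, full exclusion ledger);
* X-linked zygosity coding from CSV or VCF, allele-frequency estimation,
  and Hardy-Weinberg expectations (q, 2q(1−q), q²);
* threshold re-derivation by balanced-Gini recursive partitioning;
* stratified evaluation (prevalence / precision / recall per sex ×
  zygosity task × cohort, rank-based AUROC with bootstrap SD);
* the population-application stage: Kaplan-Meier 20-year diabetic
  retinopathy incidence by screening stratum, adjusted Cox hazard
  ratios, absolute risk difference and number needed to harm;
* a seeded synthetic EHR cohort generator, since the real cohorts are
  access-controlled.

See `docs/methods.md` for the model details and assumptions.

## Worked example

```python
import g6pdscreen as g

bundle = g.generate_cohort(g.SyntheticConfig(n_participants=6000, seed=11))
rows, ledger = g.build_cohort(bundle.participants, bundle.draws, bundle.genotypes)
print(ledger.as_dict())
grid = g.evaluate_stratified(rows, g.classify_table(rows))
print(grid[grid.cohort == "Overall"]
      [["task", "criterion", "prevalence_pct", "recall_pct", "precision_pct"]]
      .round(1).to_string(index=False))
```

prints

```
{'n_input': 6000, 'no_genotype': 0, 'missing_labs': 0, 'no_eligible_draw': 229,
 'retained': 5771, 'draws_dropped_missing': 0, 'draws_dropped_glucose_range': 1384}
             task criterion  prevalence_pct  recall_pct  precision_pct
  male_hemizygote  possible            12.2       100.0           13.5
  male_hemizygote    likely            12.2        49.6           55.1
       female_hom  possible             1.4       100.0            1.5
       female_hom    likely             1.4        67.5            9.4
female_het_or_hom  possible            22.8        97.4           24.4
female_het_or_hom    likely            22.8        24.0           55.9
```

Reading the male hemizygote rows: the OR rule catches every carrier
(recall 100%) at low precision, while the AND rule trades recall (49.6%)
for a 55.1% precision — a 4.5-fold enrichment over the 12.2% prevalence.
Heterozygous females (inside the `female_het_or_hom` task) are the hard
case: their X-inactivation-attenuated shifts leave the rules much weaker.
The exclusion ledger always reconciles: 229 participants had no draw in
the 70–200 mg/dL eligibility window.

Hardy-Weinberg consistency of observed zygosity frequencies is one call:

```python
>>> round(100 * g.hwe_expected_frequencies(0.154).female_homozygote, 1)
2.4        # expected female homozygote % at a 15.4% male hemizygote frequency
>>> round(g.glucose_gap(88.0, 5.6), 1)
-26.0      # gap (mg/dL) at median male labs: glucose 88, HbA1c 5.6%
```

The same pipeline is scriptable from a shell:

```bash
g6pdscreen simulate --seed 42 --n 4000 --out fixture/
g6pdscreen build-cohort --labs fixture/labs.csv --genotypes fixture/genotypes.csv --out cohort/
g6pdscreen classify --analysis cohort/analysis.csv --out screen/
g6pdscreen evaluate --analysis cohort/analysis.csv --screen screen/screen.csv --out eval/
g6pdscreen survival --survival fixture/survival.csv --screen screen/screen.csv --out surv/
```

Every artifact is accompanied by a log embedding the tool version,
configuration hash and seed; identical inputs give byte-identical
outputs.

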