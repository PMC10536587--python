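# neovdist

Mechanistic and allometric prediction of the **volume of distribution at
steady state (Vss)** in adults and (pre)term neonates, with a complete
accuracy-evaluation framework for study-level clinical data.

## The problem

Neonatal dosing often starts from an adult Vss scaled isometrically by
body weight (the same L/kg as in adults). Neonates, however, are not
small adults: they carry more extracellular water, far less adipose
tissue, and lower plasma-protein concentrations (albumin,
alpha-1-acid glycoprotein), so the per-kg Vss of hydrophilic drugs tends
to be *higher* and that of lipophilic drugs *lower* than the adult value.
`neovdist` implements the two tissue-composition methods used by PBPK
platforms to predict Vss mechanistically from drug physicochemistry and
body composition, and the tooling needed to quantify how well either
approach — or simple body-weight scaling — predicts observed neonatal
Vss across a table of clinical studies.

## Models

For each of twelve perfused tissues a tissue:plasma partition
coefficient Kp is computed, and

```
Vss = V_plasma + V_ery · E:P + Σ_t Kp_t · V_t ,   E:P = (BP − (1 − Hct)) / Hct
```

where BP is the blood-to-plasma concentration ratio and Hct the
hematocrit. Two Kp methods are implemented:

* **Poulin & Theil with the Berezhkovskiy correction (`PT_plus`)** —
  Kp from the octanol:water partition coefficient `P = 10^LogP` acting
  on tissue neutral lipid (phospholipid counted as 30 % lipid / 70 %
  water), scaled by `fu_p / fu_t` with
  `fu_t = 1 / (1 + (1 − fu_p)/(2 fu_p))`; adipose uses the
  vegetable-oil:water coefficient of the neutral species at plasma pH
  (`log D_vo:w = 1.115·LogP − 1.35`, times the Henderson–Hasselbalch
  neutral fraction) and unit tissue binding.
* **Rodgers & Rowland (`RR`)** — tissues split into extra- and
  intracellular water with pH-dependent partitioning of ionized species;
  moderate-to-strong bases (basic pKa ≥ 7) bind acidic phospholipids
  with an association constant back-calculated from the
  erythrocyte:unbound-plasma ratio
  `Kpu_BC = (Hct − 1 + BP)/(Hct·fu_p)`; acids, weak bases and neutrals
  bind extracellular protein with a constant back-calculated from
  `1/fu_p`. Reported `Kp = Kpu · fu_p`.

The allometric comparator predicts
`Vss_neo = Vss_adult,per-kg · (BW_neo/BW_adult)^(α−1)` (α = 1 is
isometric scaling). Accuracy is summarized by the fold error
`FE = pred/obs` per study, the geometric-mean **AFE** (bias), the
**AAFE** `10^(mean |log10 FE|)` (overall error, ≥ 1) and the percentage
of studies within two-fold.

A transparent YAML physiology (`src/neovdist/data/physiology.yaml`)
provides adult, term-neonate and preterm-neonate tissue volumes and
compositions plus protein-ontogeny scalars; the neonatal fraction
unbound is rescaled from the adult value via the ratio of the drug's
main binding protein. A 24-drug reference parameter table ships with the
package, and a synthetic clinical-study generator emulates the structure
of the neonatal literature (study sizes 3–875, term/preterm/mixed
populations, missing body weights / gestational ages / preterm
proportions, lognormal between-study noise).

## Worked example

```python
import neovdist as nv
from neovdist.synthetic_data import GeneratorConfig, generate_studies

drugs = nv.packaged_drug_table()
phys = nv.default_physiology()
adult = nv.adult_reference_vss(drugs, "PT_plus", phys)

cfg = GeneratorConfig(n_studies_per_drug=2, n_range=(3, 40), seed=1)
studies = generate_studies(cfg, adult, drugs, phys)

model = nv.NeonatalVssModel(studies, drugs, physiology=phys,
                            methods=("isometric", "allometric", "PT_plus", "RR"),
                            adult_vss=adult, reps=5)
results = model.fit(seed=1)
print(results.summary())
print("optimal alpha:", results.sweep().optimal_alpha)
```

prints

```
Neonatal Vss prediction accuracy
================================================================
studies: 48   drugs: 24   seed: 1
allometric exponent: 0.85   trial reps: 5
----------------------------------------------------------------
method          n       AFE      AAFE   within 2-fold
isometric      48     0.605     1.657           79.2%
allometric     48     0.979     1.202           97.9%
PT_plus        48     0.560     1.784           70.8%
RR             48     0.526     2.412           35.4%
----------------------------------------------------------------
optimal alpha: 0.85
```

The synthetic studies here were generated from an allometric truth with
exponent 0.85 and lognormal noise, so isometric scaling (α = 1)
underpredicts on average (AFE 0.61), the matched allometric comparator
is nearly unbiased (AFE 0.98), and the exponent sweep recovers the
generating exponent. The mechanistic methods predict from tissue
composition alone and therefore deviate from the allometric truth; on
such data they quantify how far composition-based predictions sit from a
weight-only law. `results.covariate_tests(method)` adds the LogP linear
model and Kruskal–Wallis tests on the fold errors, and
`results.plot_fold_errors(method)` draws the per-drug fold-error chart.

The same pipeline is scriptable from the shell:

```
neovdist generate --seed 7 --out out/
neovdist predict  --config run.yaml --seed 7 --out out/
neovdist evaluate --config run.yaml --seed 7 --out out/
neovdist sweep    --config run.yaml --seed 7 --out out/
neovdist theoretical --seed 7 --out out/
```

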