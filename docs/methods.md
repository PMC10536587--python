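# Methods

This note documents the models implemented in `neovdist`, the parameter
choices that matter, what the synthetic data emulate, and the package's
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and model structure

The package predicts the steady-state volume of distribution
(Vss, L and L/kg) of small-molecule drugs in three virtual populations —
adults (20–25 y), term neonates and preterm neonates (postnatal age ≤ 60
days; preterm defined as gestational age < 37 weeks) — and evaluates
those predictions against study-level clinical observations. Whole-body
Vss is assembled from tissue:plasma partition coefficients (Kp) over
twelve perfused tissues (adipose, bone, brain, gut, pancreas, heart,
kidney, liver, lung, muscle, skin, spleen) plus plasma and an
erythrocyte compartment:

```
Vss = V_plasma + V_ery · E:P + Σ_t Kp_t · V_t
E:P = (BP − (1 − Hct)) / Hct
```

Distribution is assumed perfusion-limited, linear and
transporter-free; clearance and dose do not enter (Vss is modelled as a
dose- and clearance-independent parameter), so no concentration–time
solver exists or is needed.

Including the erythrocyte term is a deliberate choice: BP is a required
drug input, and omitting red cells would understate Vss for BP > 1
drugs. When BP < 1 − Hct (a drug excluded from red cells more strongly
than plasma water allows), E:P is floored at 0 with a warning in the
summation path; the Rodgers & Rowland base branch instead raises an
explicit "BP inconsistent with hematocrit" error, because there the
quantity enters a back-calculated association constant and silently
clamping would fabricate binding.

## Partition-coefficient methods

### Poulin & Theil with Berezhkovskiy correction (`PT_plus`)

For non-adipose tissue t and plasma p, with `P = 10^LogP`:

```
Kp_t = [P(f_nl,t + 0.3 f_ph,t) + (f_w,t + 0.7 f_ph,t)]
     / [P(f_nl,p + 0.3 f_ph,p) + (f_w,p + 0.7 f_ph,p)] · fu_p / fu_t
fu_t = 1 / (1 + (1 − fu_p) / (2 fu_p))
```

(phospholipid behaves as 30 % neutral lipid / 70 % water). Adipose
substitutes the vegetable-oil:water distribution coefficient of the
neutral species at plasma pH, `D_vo:w = 10^(1.115·LogP − 1.35) · f_ni(7.4)`,
and uses fu_t = 1 (no binding protein in adipose interstitium). The
neutral fraction `f_ni` follows Henderson–Hasselbalch forms per
ionization class (monoprotic/diprotic acids and bases, ampholytes;
ampholytes store the acidic then the basic pKa).

### Rodgers & Rowland (`RR`)

Unbound partition coefficients per tissue, `Kp = Kpu · fu_p`, with
ionization factors `X(pH) = 1 / f_ni(pH)` evaluated at plasma pH (7.4),
intracellular pH (7.0) and erythrocyte pH (7.22):

```
Kpu_t = f_EW,t + (X_iw / X_p) · f_IW,t + [P·f_nl,t + (0.3P + 0.7)·f_ph,t] / X_p
        + binding term
```

* **Moderate-to-strong bases** (most basic pKa ≥ 7, including the basic
  centre of ampholytes): the binding term is
  `Ka_AP · AP_t · 10^(pKa − pH_iw) / X_p`, with Ka_AP back-calculated
  from the erythrocyte:unbound-plasma ratio
  `Kpu_BC = (Hct − 1 + BP)/(Hct · fu_p)` after subtracting the
  erythrocyte water and lipid contributions. Requires BP > 1 − Hct.
* **Acids, weak bases, neutrals**: the binding term is `Ka_PR · PR_t`,
  where `Ka_PR = 1/fu_p − 1 − lipid_term(plasma)/X_p` and PR_t is the
  tissue:plasma concentration ratio of the binding protein — the albumin
  ratio for protein-bound ionized drugs, the lipoprotein ratio for
  neutral compounds.

Adipose again uses `D_vo:w` in place of P. Two numerical guards are
documented behaviour, not silent fixes: a negative back-calculated
association constant (physically impossible, arising when the lipid
term already exceeds the observed binding, e.g. very lipophilic
low-fu neutrals) is clamped to zero with a logged warning; and an
**ampholyte** whose BP ≤ 1 − Hct (in the shipped table: meropenem,
BP 0.507) cannot support the erythrocyte back-calculation, so it falls
back to the protein-binding branch with a logged warning rather than
failing — for true bases the error is raised, as the precondition is
then unambiguous.

The base/non-base dispatch threshold (pKa 7) is configurable
(`strong_base_threshold`). All method constants (0.3/0.7 phospholipid
weights, oil:water correlation, pH defaults, the pKa threshold) live in
`neovdist/constants.py`.

## Physiology

`data/physiology.yaml` is a transparent, literature-informed
approximation written for this package; it is **not** a copy of any
commercial simulator's virtual populations, and no test assumes
equivalence with one. Its content:

* **Adult tissue composition** (water split extra-/intracellular,
  neutral lipid, neutral phospholipid, acidic phospholipid mg/g,
  albumin and lipoprotein tissue:plasma ratios) follows the standard
  tabulations used with the partition methods.
* **Tissue volumes** are fractions of body weight per population, with
  breakpoints interpolated over gestational age (preterm), postnatal
  age (term) or age (adult). Key ontogeny: adipose ≈ 19 % of BW in
  adults, ≈ 13.5 % at term (PNA 7 d), ≈ 3 % at GA 30 w; neonatal skin
  ≈ 13 % of BW versus ≈ 4 % in adults; neonatal brain ≈ 10 % versus
  2 %. The modelled compartments sum to ~0.91 of body volume in adults
  and ~0.70–0.84 in neonates; unmodelled residual mass is a documented
  approximation.
* **Composition ontogeny** is applied as per-population scalars:
  extracellular tissue water ×1.35 (term) / ×1.60 (preterm), neutral
  lipid ×0.55 (term) / ×0.35 (preterm) — neonatal tissues are
  water-rich and lipid-poor (the neonatal brain in particular is
  largely unmyelinated). Total water is capped at 0.94 with
  proportional renormalization.
* **Blood**: hematocrit 0.45 / 0.50 / 0.47 (adult / term / preterm);
  plasma pH 7.4, intracellular pH 7.0, erythrocyte pH 7.22.
* **Protein ontogeny**: neonate:adult ratios — albumin 0.75 (term) /
  0.65 (preterm), alpha-1-acid glycoprotein 0.45 / 0.35. The neonatal
  fraction unbound is `fu_n = 1 / (1 + ((1 − fu_a)/fu_a) · R)` with R
  the ratio of the drug's main binding protein.
* **Growth**: body weight by GA at birth (0.65 kg at 24 w to 2.8 kg at
  36 w) or PNA (3.5 kg at term birth to 5.0 kg at 60 d), with 1.5 %/day
  postnatal gain beyond day 7 for preterms.

Virtual subjects sample GA/PNA uniformly within the study range, sex as
Bernoulli(proportion female), and apply lognormal inter-individual
variability (default CV 15 %) to body weight and, as a relative
perturbation renormalized to conserve total modelled volume, to tissue
fractions. When a study reports a mean body weight, sampled weights are
rescaled so their median matches it. With the variability CV set to 0
the simulation collapses to the deterministic reference subject at the
covariate midpoints — this is the documented meaning of "zero
inter-individual variability" and what makes noise-free end-to-end
checks exact.

## Trial simulation and evaluation

* **Theoretical simulations**: 50 male + 50 female subjects per
  population at fixed covariates (preterm at GA 30 w, term at PNA 7 d,
  adults 20–25 y); neonatal cohort means are expressed as fold changes
  over the adult cohort mean.
* **Trial-mimicking simulations**: matched to each study's n,
  proportion female, PNA range and (preterm only) GA range; ten
  repetitions by default, arithmetic mean of per-subject per-kg Vss
  within a repetition and across repetitions (geometric averaging is
  available behind a flag). Mixed studies simulate both populations and
  combine them weighted by the preterm proportion; an unknown
  proportion is taken as 0.5, and studies without reported GA are
  treated as term.
* **Analysis conventions**: missing study body weight is imputed by
  population (1.19 / 3.23 / 2.44 kg for preterm / term / mixed); the
  adult body weight for scaling is fixed at 70 kg. AFE is the geometric
  mean of the fold errors; AAFE uses |log10 FE| (without the absolute
  value the two would coincide, which contradicts the definition of an
  error irrespective of direction); the two-fold interval is inclusive
  at both ends. The exponent sweep covers 0.75–1.00 in steps of 0.025
  (fine enough to distinguish 0.85 from 0.90), and the optimum is the
  exponent minimizing |log10 AFE| with ties broken toward the larger
  exponent; AAFE- and two-fold-optimal exponents are also reported.
* **Covariate tests** operate on study-level log10 fold errors: OLS
  slope t-test for LogP (scipy's linear regression), Kruskal–Wallis
  with tie correction for ionization type and population composition.
  Drug-level geometric means are also available; no multiple-testing
  correction is applied.

## Synthetic data

The generator emulates the *structure* of the neonatal Vss literature,
not any particular dataset: study sizes log-uniform on [3, 875]
(so small studies dominate, median ≈ 50), populations ≈ 36/34/30 %
term/preterm/mixed, missing body weight 10 %, missing GA 15 %
(term/mixed), unknown preterm proportion 30 % of mixed studies, and
between-study lognormal noise with sigma_log10 = 0.15 (a two-sigma
spread of about 2-fold, comparable to the per-drug spread real studies
show). Observed Vss is a truth model times noise; the truth is computed
from the same analysis conventions the evaluator applies (imputation
constants, equal-split and term assumptions), so with zero noise every
pipeline stage reproduces the truth exactly — that is what the
end-to-end tests assert. What passing these tests shows is internal
consistency and correct plumbing, *not* agreement of the physiology
with real neonates: the generator contains no disease effects, no
ecological bias between study-level and individual-level covariates,
and noise that is homoscedastic on the log scale by construction.

## Numerical and scale choices

* Problem sizes in the checked pipelines (cohorts of 100, ten trial
  repetitions, up to 60 subjects per synthetic study in the
  trial-mimicking cohort, 240 studies in the sweep cohort) were chosen
  as the smallest sizes at which the Monte-Carlo summaries are stable
  to well under the tolerances asserted.
* All randomness flows from `numpy.random.default_rng` seeded
  explicitly; per-study seeds are spawned from the run seed, so runs
  are bitwise reproducible and studies are statistically independent.
* Validation is eager and named: drug rows, study records, population
  specs and compositions raise on construction with the offending field
  in the message; boundary cases (fu = 0, BP ≤ 0, n < 3, PNA > 60 d,
  GA/label inconsistency) are errors, not warnings.

## Limitations

* The physiology tables are documented approximations; absolute
  neonatal predictions inherit their uncertainty, and only directional
  behaviour (more water → hydrophilic Vss up; less fat → lipophilic
  Vss down; lower protein → higher fu) should be read as robust.
* Perfusion-limited, transporter-free distribution; no disease states
  (sepsis, ECMO, hypothermia are out of scope by design).
* The allometric comparator uses study-mean body weights and a fixed
  70 kg adult; exponent estimates from aggregated data are subject to
  ecological bias.
* Adult anchor values for the scaling comparators default to the
  package's own mechanistic adult predictions; users with measured
  adult Vss values should pass them via `adult_vss`.
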