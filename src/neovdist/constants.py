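"""Method constants shared by the tissue-composition Kp methods.

Every number here is a property of the *methods*, not of a drug or a
subject, and is kept in one place so it can be audited against the source
publications of the Poulin & Theil (+ Berezhkovskiy) and Rodgers & Rowland
partition-coefficient models.
"""

# Fraction of phospholipid that behaves like neutral lipid (rest like water)
# in the Poulin & Theil tissue "solvent" decomposition.
PHOSPHOLIPID_LIPID_FRACTION = 0.3
PHOSPHOLIPID_WATER_FRACTION = 0.7

# Vegetable(olive)-oil:water partition correlation for the neutral species,
# log D_vo:w = VOW_SLOPE * logP + VOW_INTERCEPT (Leo-type correlation used
# by the Poulin & Theil adipose term).
VOW_SLOPE = 1.115
VOW_INTERCEPT = -1.35

# Default pH values (conventional to the Rodgers & Rowland source; the
# physiology configuration may override them).
PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_ERYTHROCYTE = 7.22

# pKa threshold above which a basic centre is treated by the
# moderate-to-strong-base branch of Rodgers & Rowland (acidic-phospholipid
# binding parameterized from the blood-to-plasma ratio).
STRONG_BASE_PKA_THRESHOLD = 7.0

# Adult reference body weight used by the allometric comparator (kg).
ADULT_BW_KG = 70.0

# Body-weight imputation constants for studies that do not report a mean
# body weight, by neonatal population label (kg).
IMPUTED_BW_KG = {"preterm": 1.19, "term": 3.23, "mixed": 2.44}

# Gestational-age threshold defining prematurity (weeks) and the maximum
# postnatal age defining a neonate (days).
PRETERM_GA_THRESHOLD_WEEKS = 37.0
NEONATE_PNA_MAX_DAYS = 60.0
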