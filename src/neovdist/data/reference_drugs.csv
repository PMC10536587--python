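name,mwt_g_mol,logp,ionization_type,pka1,pka2,fu,binding_protein,bp,bp_source
Acetaminophen,151,0.76,monoprotic_acid,9.7,,0.520,HSA,1.04,measured
Alfentanil,417,2.80,monoprotic_base,6.5,,0.086,AGP,0.63,measured
Amoxicillin,365,0.42,ampholyte,2.4,9.6,0.850,HSA,1.04,measured
Caffeine,194,0.08,neutral,,,0.640,HSA,1.00,measured
Cefazolin,455,-1.20,monoprotic_acid,2.1,,0.180,HSA,0.60,measured
Cefepime,481,-3.60,monoprotic_acid,2.8,,0.780,HSA,0.74,measured
Cefotaxime,455,-0.05,monoprotic_acid,3.4,,0.600,HSA,1.00,assumed
Ceftazidime,547,-1.70,diprotic_acid,1.8,2.7,0.790,HSA,0.72,measured
Ceftriaxone,555,-3.20,diprotic_acid,3.2,4.1,0.100,HSA,1.00,assumed
Dexmedetomidine,200,2.80,monoprotic_base,6.5,,0.060,HSA,0.80,predicted
Fentanyl,336,4.10,monoprotic_base,8.4,,0.160,HSA,0.99,measured
Flucloxacillin,454,2.80,monoprotic_acid,2.7,,0.043,HSA,1.00,assumed
Imipenem,299,-0.81,ampholyte,3.4,10.9,0.860,HSA,1.00,assumed
Levetiracetam,170,-0.48,neutral,,,0.900,HSA,0.69,predicted
Lidocaine,234,2.70,monoprotic_base,7.8,,0.330,AGP,0.78,measured
Meperidine,247,3.00,monoprotic_base,8.7,,0.420,HSA,1.01,measured
Meropenem,383,-1.00,ampholyte,3.3,9.4,0.870,HSA,0.507,measured
Midazolam,326,3.10,monoprotic_base,6.2,,0.017,HSA,0.68,measured
Morphine,285,1.10,monoprotic_base,8.0,,0.650,HSA,1.00,measured
Phenobarbital,232,1.30,monoprotic_acid,7.4,,0.490,HSA,0.99,measured
Piperacillin,518,0.84,monoprotic_acid,3.5,,0.500,HSA,0.65,measured
Propofol,178,4.20,neutral,,,0.016,HSA,1.25,measured
Remifentanil,376,2.30,monoprotic_base,7.5,,0.300,AGP,0.90,predicted
Sufentanil,387,3.90,monoprotic_base,8.0,,0.075,AGP,0.74,measured
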