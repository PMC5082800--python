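category,source,hr,ci_low,ci_high,weight,provenance
Myocardial infarction,combined,,,,1,comparator-synthetic
Congestive heart failure,combined,,,,1,comparator-synthetic
Peripheral vascular disease,combined,,,,1,comparator-synthetic
Cerebrovascular disease,combined,,,,1,comparator-synthetic
Dementia,combined,,,,1,comparator-synthetic
Chronic pulmonary disease,combined,,,,1,comparator-synthetic
Connective tissue disease,combined,,,,1,comparator-synthetic
Peptic ulcer disease,combined,,,,1,comparator-synthetic
Mild liver disease,combined,,,,1,comparator-synthetic
Diabetes,combined,,,,1,comparator-synthetic
Diabetes with complications,combined,,,,2,comparator-synthetic
Hemiplegia,combined,,,,2,comparator-synthetic
Renal disease,combined,,,,2,comparator-synthetic
Any malignancy,combined,,,,2,comparator-synthetic
Moderate or severe liver disease,combined,,,,3,comparator-synthetic
Metastatic solid tumour,combined,,,,6,comparator-synthetic
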