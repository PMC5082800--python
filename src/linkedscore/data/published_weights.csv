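category,source,hr,ci_low,ci_high,weight,provenance
Neoplasm histology,combined,1.2,1.0,1.3,1,published
Malignancy of digestive organs and peritoneum,icd,1.8,1.6,2.1,6,published
Malignancy of respiratory tract and intrathoracic organs,combined,3.5,3.0,4.0,12,published
Malignancy of genitourinary organ,icd,1.5,1.3,1.6,4,published
Malignancy of other and unspecified sites,icd,1.8,1.5,2.3,6,published
Malignancy of lymphatic and haemopoietic tissue,combined,1.5,1.3,1.8,4,published
Metastases,combined,2.9,2.5,3.3,11,published
Non thyroid and non-diabetic endocrine gland disease,icd,1.5,1.2,1.9,4,published
Diabetes,combined,1.1,1.0,1.2,1,published
Non deficiency and non-haemolytic anaemias,combined,1.1,1.0,1.2,1,published
Non-malignant white cell platelet and splenic disorders,combined,1.2,1.0,1.4,2,published
Non-organic psychoses,combined,1.3,1.2,1.5,3,published
Other central nervous system disorders,combined,1.4,1.0,1.9,3,published
Epilepsy,combined,1.2,1.1,1.4,2,published
Paralysis,combined,1.2,1.1,1.4,2,published
Dementia,combined,1.4,1.2,1.6,4,published
Dementia,icd,2.0,1.8,2.2,7,published
Parkinson's disease,combined,1.5,1.3,1.7,4,published
Spinal disease,combined,1.5,1.2,2.0,4,published
Multiple sclerosis,icd,2.4,1.7,3.5,9,published
Heart conduction disorders,combined,1.2,1.1,1.2,2,published
Cerebrovascular disease,combined,1.2,1.1,1.3,2,published
Peripheral vascular disease,combined,1.1,1.0,1.2,1,published
Peripheral vascular disease,icd,1.4,1.2,1.5,3,published
Heart failure,combined,1.4,1.3,1.5,3,published
Chronic obstructive pulmonary disease,combined,1.1,1.0,1.2,1,published
Chronic obstructive pulmonary disease,icd,1.5,1.3,1.6,4,published
Lung disease due to external agents,combined,1.6,1.2,2.0,5,published
Pleural disease,combined,1.1,1.0,1.2,1,published
Interstitial lung disease,combined,1.5,1.3,1.8,4,published
Oesophageal stomach and duodenal diseases,combined,1.1,1.0,1.2,1,published
Liver disease,combined,1.4,1.1,1.7,3,published
Cirrhosis,combined,1.6,1.3,2.1,5,published
Nephritis nephrosis and nephrotic syndrome,combined,1.3,1.2,1.4,2,published
Connective tissue diseases,icd,2.9,1.1,8.0,11,published
Congenital musculoskeletal deformities,icd,17.3,2.8,108.2,29,published
Chromosomal anomalies,combined,2.0,1.1,3.4,7,published
Burns,combined,1.2,1.0,1.5,2,published
Alcohol or illegal drug use,combined,1.3,1.1,1.5,3,published
Alcohol or illegal drug use,icd,1.8,1.5,2.1,6,published
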