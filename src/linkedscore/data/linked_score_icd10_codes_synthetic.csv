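category_label,code
Neoplasm histology,D37
Neoplasm histology,D38
Neoplasm histology,D39
Malignancy of digestive organs and peritoneum,C15
Malignancy of digestive organs and peritoneum,C16
Malignancy of digestive organs and peritoneum,C18
Malignancy of digestive organs and peritoneum,C25
Malignancy of respiratory tract and intrathoracic organs,C33
Malignancy of respiratory tract and intrathoracic organs,C34
Malignancy of genitourinary organ,C61
Malignancy of genitourinary organ,C64
Malignancy of genitourinary organ,C67
Malignancy of other and unspecified sites,C76
Malignancy of other and unspecified sites,C80
Malignancy of lymphatic and haemopoietic tissue,C81
Malignancy of lymphatic and haemopoietic tissue,C85
Malignancy of lymphatic and haemopoietic tissue,C90
Malignancy of lymphatic and haemopoietic tissue,C91
Metastases,C77
Metastases,C78
Metastases,C79
Non thyroid and non-diabetic endocrine gland disease,E20
Non thyroid and non-diabetic endocrine gland disease,E21
Non thyroid and non-diabetic endocrine gland disease,E24
Non thyroid and non-diabetic endocrine gland disease,E27
Diabetes,E10
Diabetes,E11
Diabetes,E14
Non deficiency and non-haemolytic anaemias,D60
Non deficiency and non-haemolytic anaemias,D61
Non deficiency and non-haemolytic anaemias,D63
Non deficiency and non-haemolytic anaemias,D64
Non-malignant white cell platelet and splenic disorders,D69
Non-malignant white cell platelet and splenic disorders,D70
Non-malignant white cell platelet and splenic disorders,D73
Non-organic psychoses,F20
Non-organic psychoses,F22
Non-organic psychoses,F25
Non-organic psychoses,F29
Other central nervous system disorders,G93
Other central nervous system disorders,G96
Epilepsy,G40
Epilepsy,G41
Paralysis,G81
Paralysis,G82
Paralysis,G83
Dementia,F00
Dementia,F01
Dementia,F03
Parkinson's disease,G20
Parkinson's disease,G21
Spinal disease,M47
Spinal disease,M48
Multiple sclerosis,G35
Multiple sclerosis,G36
Multiple sclerosis,G37
Heart conduction disorders,I44
Heart conduction disorders,I45
Heart conduction disorders,I47
Heart conduction disorders,I49
Cerebrovascular disease,I60
Cerebrovascular disease,I63
Cerebrovascular disease,I64
Cerebrovascular disease,I69
Peripheral vascular disease,I70
Peripheral vascular disease,I73
Heart failure,I50
Heart failure,I50.0
Heart failure,I50.1
Chronic obstructive pulmonary disease,J43
Chronic obstructive pulmonary disease,J44
Lung disease due to external agents,J60
Lung disease due to external agents,J62
Lung disease due to external agents,J68
Pleural disease,J90
Pleural disease,J92
Pleural disease,J94
Interstitial lung disease,J84
Interstitial lung disease,J84.1
Oesophageal stomach and duodenal diseases,K21
Oesophageal stomach and duodenal diseases,K25
Oesophageal stomach and duodenal diseases,K27
Liver disease,K75
Liver disease,K76
Cirrhosis,K70
Cirrhosis,K70.3
Cirrhosis,K74
Nephritis nephrosis and nephrotic syndrome,N00
Nephritis nephrosis and nephrotic syndrome,N03
Nephritis nephrosis and nephrotic syndrome,N05
Connective tissue diseases,M30
Connective tissue diseases,M32
Connective tissue diseases,M34
Congenital musculoskeletal deformities,Q65
Congenital musculoskeletal deformities,Q67
Congenital musculoskeletal deformities,Q68
Congenital musculoskeletal deformities,Q79
Chromosomal anomalies,Q90
Chromosomal anomalies,Q91
Chromosomal anomalies,Q93
Burns,T20
Burns,T21
Burns,T31
Alcohol or illegal drug use,F10
Alcohol or illegal drug use,F11
Alcohol or illegal drug use,F19
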