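category_label,code
Myocardial infarction,I21
Myocardial infarction,I22
Congestive heart failure,I50
Peripheral vascular disease,I70
Peripheral vascular disease,I73
Cerebrovascular disease,I60
Cerebrovascular disease,I63
Dementia,F00
Dementia,F03
Chronic pulmonary disease,J43
Chronic pulmonary disease,J44
Connective tissue disease,M32
Connective tissue disease,M34
Peptic ulcer disease,K25
Peptic ulcer disease,K27
Mild liver disease,K76
Diabetes,E11
Diabetes with complications,E10.2
Hemiplegia,G81
Renal disease,N18
Any malignancy,C34
Moderate or severe liver disease,K70.3
Metastatic solid tumour,C78
Metastatic solid tumour,C79
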