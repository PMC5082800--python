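category_label,code
Myocardial infarction,G30..
Myocardial infarction,G301.
Congestive heart failure,G58..
Peripheral vascular disease,G73..
Cerebrovascular disease,G66..
Dementia,E00..
Chronic pulmonary disease,H31..
Chronic pulmonary disease,H32..
Connective tissue disease,N04..
Peptic ulcer disease,J11..
Mild liver disease,J60..
Diabetes,C10..
Diabetes with complications,C104.
Hemiplegia,F22..
Renal disease,K05..
Any malignancy,B22..
Moderate or severe liver disease,J616.
Metastatic solid tumour,B57..
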