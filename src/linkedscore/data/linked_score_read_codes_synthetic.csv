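category_label,code
Neoplasm histology,BB2..
Neoplasm histology,BB3..
Malignancy of respiratory tract and intrathoracic organs,B22..
Malignancy of respiratory tract and intrathoracic organs,B221.
Malignancy of respiratory tract and intrathoracic organs,B222.
Malignancy of lymphatic and haemopoietic tissue,B62..
Malignancy of lymphatic and haemopoietic tissue,B63..
Metastases,B56..
Metastases,B57..
Diabetes,C10..
Diabetes,C108.
Diabetes,C109.
Non deficiency and non-haemolytic anaemias,D20..
Non deficiency and non-haemolytic anaemias,D21..
Non-malignant white cell platelet and splenic disorders,D40..
Non-malignant white cell platelet and splenic disorders,D41..
Non-organic psychoses,E10..
Non-organic psychoses,E11..
Other central nervous system disorders,F14..
Other central nervous system disorders,F15..
Epilepsy,F25..
Epilepsy,F250.
Paralysis,F22..
Paralysis,F23..
Dementia,E00..
Dementia,E001.
Dementia,E012.
Parkinson's disease,F12..
Parkinson's disease,F120.
Spinal disease,N11..
Spinal disease,N12..
Heart conduction disorders,G57..
Heart conduction disorders,G571.
Cerebrovascular disease,G64..
Cerebrovascular disease,G66..
Peripheral vascular disease,G73..
Peripheral vascular disease,G730.
Heart failure,G58..
Heart failure,G580.
Chronic obstructive pulmonary disease,H31..
Chronic obstructive pulmonary disease,H32..
Lung disease due to external agents,H41..
Lung disease due to external agents,H42..
Pleural disease,H51..
Pleural disease,H52..
Interstitial lung disease,H56..
Interstitial lung disease,H563.
Oesophageal stomach and duodenal diseases,J10..
Oesophageal stomach and duodenal diseases,J11..
Liver disease,J60..
Liver disease,J613.
Cirrhosis,J61..
Cirrhosis,J615.
Cirrhosis,J616.
Nephritis nephrosis and nephrotic syndrome,K01..
Nephritis nephrosis and nephrotic syndrome,K02..
Chromosomal anomalies,PJ0..
Chromosomal anomalies,PJ3..
Burns,S90..
Burns,S91..
Alcohol or illegal drug use,E23..
Alcohol or illegal drug use,E24..
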