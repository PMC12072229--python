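# Observed changes in adefovir pharmacokinetics with renal impairment after a
# single oral 10 mg adefovir-dipivoxil dose (Hepsera Clinical Pharmacology and
# Biopharmaceutics Review; 33 subjects stratified by creatinine clearance).
metric,value,units,citation
clr_healthy,12.67,L/h,"Hepsera Clinical Pharmacology review (US FDA)"
clr_severe,2.09,L/h,"Hepsera Clinical Pharmacology review (US FDA)"
clr_fold_decrease,6.1,fold,"Hepsera Clinical Pharmacology review (US FDA)"
cmax_fold_increase,2.9,fold,"Hepsera Clinical Pharmacology review (US FDA)"
auc_fold_increase,6.2,fold,"Hepsera Clinical Pharmacology review (US FDA)"
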