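# Observed within-study ratios (probenecid phase / control phase) of adefovir
# PK parameters, computed from the reported mean parameters of the crossover
# DDI study in six Japanese men (Maeda et al. 2014, probenecid given 2 h
# before 10 mg adefovir-dipivoxil).
phase,metric,observed_ratio,citation
probenecid-0.5g,cmax,1.08,"Maeda et al. 2014, crossover DDI study"
probenecid-0.5g,auc,1.04,"Maeda et al. 2014, crossover DDI study"
probenecid-0.5g,clr,0.85,"Maeda et al. 2014, crossover DDI study"
probenecid-0.75g,cmax,2.04,"Maeda et al. 2014, crossover DDI study"
probenecid-0.75g,auc,2.09,"Maeda et al. 2014, crossover DDI study"
probenecid-0.75g,clr,0.44,"Maeda et al. 2014, crossover DDI study"
probenecid-1.5g,cmax,1.81,"Maeda et al. 2014, crossover DDI study"
probenecid-1.5g,auc,1.82,"Maeda et al. 2014, crossover DDI study"
probenecid-1.5g,clr,0.52,"Maeda et al. 2014, crossover DDI study"
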