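# SYNTHETIC observed-summary stand-in for the nine adefovir
# verification studies (29 AUC, 22 Cmax, 8 CLr measurements).
# Values were generated by scripts/make_observed_summaries.py from
# the bundled adefovir model with seeded log-normal noise (CV 12%);
# they are NOT the historical clinical measurements.
study,arm,population,route,dose_mg,per_kg,n_doses,analysis,metric,value,units,citation
cundy-iv,iv-1.0mgkg,white,iv,1.0,1,28,d1,auc_0_24,4687.611,ng.h/mL,synthetic stand-in for the cundy-iv study arm
cundy-iv,iv-1.0mgkg,white,iv,1.0,1,28,d1,cmax,3001.168,ng/mL,synthetic stand-in for the cundy-iv study arm
cundy-iv,iv-1.0mgkg,white,iv,1.0,1,28,ss,auc_ss,3968.77,ng.h/mL,synthetic stand-in for the cundy-iv study arm
cundy-iv,iv-1.0mgkg,white,iv,1.0,1,28,ss,cmax,2581.541,ng/mL,synthetic stand-in for the cundy-iv study arm
cundy-iv,iv-1.0mgkg,white,iv,1.0,1,28,ss,clr,17.801,L/h,synthetic stand-in for the cundy-iv study arm
cundy-iv,iv-3.0mgkg,white,iv,3.0,1,28,d1,auc_0_24,14876.709,ng.h/mL,synthetic stand-in for the cundy-iv study arm
cundy-iv,iv-3.0mgkg,white,iv,3.0,1,28,d1,cmax,7627.126,ng/mL,synthetic stand-in for the cundy-iv study arm
cundy-iv,iv-3.0mgkg,white,iv,3.0,1,28,ss,auc_ss,16570.681,ng.h/mL,synthetic stand-in for the cundy-iv study arm
cundy-iv,iv-3.0mgkg,white,iv,3.0,1,28,ss,cmax,8208.41,ng/mL,synthetic stand-in for the cundy-iv study arm
cundy-iv,iv-3.0mgkg,white,iv,3.0,1,28,ss,clr,18.468,L/h,synthetic stand-in for the cundy-iv study arm
trueck,po-10mg,white,oral,10.0,0,1,d1,auc_0_24,148.322,ng.h/mL,synthetic stand-in for the trueck study arm
trueck,po-10mg,white,oral,10.0,0,1,d1,auc_inf,154.462,ng.h/mL,synthetic stand-in for the trueck study arm
trueck,po-10mg,white,oral,10.0,0,1,d1,cmax,15.69,ng/mL,synthetic stand-in for the trueck study arm
trueck,po-10mg,white,oral,10.0,0,1,d1,clr,15.857,L/h,synthetic stand-in for the trueck study arm
kearney,po-10mg,white,oral,10.0,0,1,d1,auc_0_24,169.604,ng.h/mL,synthetic stand-in for the kearney study arm
kearney,po-10mg,white,oral,10.0,0,1,d1,auc_inf,161.093,ng.h/mL,synthetic stand-in for the kearney study arm
kearney,po-10mg,white,oral,10.0,0,1,d1,cmax,14.809,ng/mL,synthetic stand-in for the kearney study arm
kearney,po-10mg,white,oral,10.0,0,1,d1,clr,14.371,L/h,synthetic stand-in for the kearney study arm
shida,po-10mg-qd,japanese,oral,10.0,0,5,d1,auc_0_24,131.459,ng.h/mL,synthetic stand-in for the shida study arm
shida,po-10mg-qd,japanese,oral,10.0,0,5,d1,cmax,14.951,ng/mL,synthetic stand-in for the shida study arm
shida,po-10mg-qd,japanese,oral,10.0,0,5,d1,clr,15.719,L/h,synthetic stand-in for the shida study arm
shida,po-10mg-qd,japanese,oral,10.0,0,5,ss,auc_ss,192.613,ng.h/mL,synthetic stand-in for the shida study arm
shida,po-10mg-qd,japanese,oral,10.0,0,5,ss,cmax,16.852,ng/mL,synthetic stand-in for the shida study arm
shida,po-10mg-qd,japanese,oral,10.0,0,5,ss,clr,13.253,L/h,synthetic stand-in for the shida study arm
sun,po-10mg,chinese,oral,10.0,0,1,d1,auc_0_24,188.752,ng.h/mL,synthetic stand-in for the sun study arm
sun,po-10mg,chinese,oral,10.0,0,1,d1,auc_inf,210.483,ng.h/mL,synthetic stand-in for the sun study arm
sun,po-10mg,chinese,oral,10.0,0,1,d1,cmax,15.667,ng/mL,synthetic stand-in for the sun study arm
sun,po-10mg,chinese,oral,10.0,0,1,d1,clr,13.431,L/h,synthetic stand-in for the sun study arm
sun,po-20mg,chinese,oral,20.0,0,1,d1,auc_0_24,366.922,ng.h/mL,synthetic stand-in for the sun study arm
sun,po-20mg,chinese,oral,20.0,0,1,d1,auc_inf,324.41,ng.h/mL,synthetic stand-in for the sun study arm
sun,po-20mg,chinese,oral,20.0,0,1,d1,cmax,41.304,ng/mL,synthetic stand-in for the sun study arm
sun,po-40mg,chinese,oral,40.0,0,1,d1,auc_0_24,728.171,ng.h/mL,synthetic stand-in for the sun study arm
sun,po-40mg,chinese,oral,40.0,0,1,d1,auc_inf,851.056,ng.h/mL,synthetic stand-in for the sun study arm
sun,po-40mg,chinese,oral,40.0,0,1,d1,cmax,58.037,ng/mL,synthetic stand-in for the sun study arm
sun,po-10mg-qd,chinese,oral,10.0,0,7,d1,cmax,15.502,ng/mL,synthetic stand-in for the sun study arm
sun,po-10mg-qd,chinese,oral,10.0,0,7,ss,auc_ss,216.559,ng.h/mL,synthetic stand-in for the sun study arm
sun,po-10mg-qd,chinese,oral,10.0,0,7,ss,cmax,17.063,ng/mL,synthetic stand-in for the sun study arm
fok,po-10mg,chinese,oral,10.0,0,1,d1,auc_0_24,187.401,ng.h/mL,synthetic stand-in for the fok study arm
fok,po-10mg,chinese,oral,10.0,0,1,d1,auc_inf,200.114,ng.h/mL,synthetic stand-in for the fok study arm
fok,po-10mg,chinese,oral,10.0,0,1,d1,cmax,13.123,ng/mL,synthetic stand-in for the fok study arm
barditch,po-125mg,white,oral,125.0,0,14,d1,auc_0_24,2325.546,ng.h/mL,synthetic stand-in for the barditch study arm
barditch,po-125mg,white,oral,125.0,0,14,d1,cmax,163.274,ng/mL,synthetic stand-in for the barditch study arm
barditch,po-125mg,white,oral,125.0,0,14,ss,auc_ss,1919.243,ng.h/mL,synthetic stand-in for the barditch study arm
barditch,po-125mg,white,oral,125.0,0,14,ss,cmax,206.507,ng/mL,synthetic stand-in for the barditch study arm
barditch,po-250mg,white,oral,250.0,0,14,d1,auc_0_24,3660.51,ng.h/mL,synthetic stand-in for the barditch study arm
barditch,po-250mg,white,oral,250.0,0,14,d1,cmax,464.612,ng/mL,synthetic stand-in for the barditch study arm
barditch,po-250mg,white,oral,250.0,0,14,ss,auc_ss,4041.66,ng.h/mL,synthetic stand-in for the barditch study arm
barditch,po-250mg,white,oral,250.0,0,14,ss,cmax,315.47,ng/mL,synthetic stand-in for the barditch study arm
barditch,po-500mg,white,oral,500.0,0,14,d1,auc_0_24,7170.736,ng.h/mL,synthetic stand-in for the barditch study arm
barditch,po-500mg,white,oral,500.0,0,14,d1,cmax,769.243,ng/mL,synthetic stand-in for the barditch study arm
barditch,po-500mg,white,oral,500.0,0,14,ss,auc_ss,9528.796,ng.h/mL,synthetic stand-in for the barditch study arm
barditch,po-500mg,white,oral,500.0,0,14,ss,cmax,747.789,ng/mL,synthetic stand-in for the barditch study arm
maeda-control,po-10mg,japanese,oral,10.0,0,1,d1,auc_0_8,97.4,ng.h/mL,synthetic stand-in for the maeda-control study arm
maeda-control,po-10mg,japanese,oral,10.0,0,1,d1,auc_inf,187.585,ng.h/mL,synthetic stand-in for the maeda-control study arm
maeda-control,po-10mg,japanese,oral,10.0,0,1,d1,cmax,17.919,ng/mL,synthetic stand-in for the maeda-control study arm
maeda-control,po-10mg,japanese,oral,10.0,0,1,d1,clr,17.144,L/h,synthetic stand-in for the maeda-control study arm
fda-healthy,po-10mg,white,oral,10.0,0,1,d1,auc_0_24,150.133,ng.h/mL,synthetic stand-in for the fda-healthy study arm
fda-healthy,po-10mg,white,oral,10.0,0,1,d1,auc_inf,148.957,ng.h/mL,synthetic stand-in for the fda-healthy study arm
fda-healthy,po-10mg,white,oral,10.0,0,1,d1,cmax,13.828,ng/mL,synthetic stand-in for the fda-healthy study arm
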