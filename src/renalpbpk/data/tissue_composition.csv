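# Tissue composition fixture, version 1.
# Fractional volumes of extracellular water (f_ew), intracellular water (f_iw),
# neutral lipid (f_nl) and neutral phospholipid (f_np); acidic phospholipid
# concentration (ap_mg_g, mg per g tissue); intracellular pH (ph_iw); and the
# tissue:plasma albumin ratio (albumin_ratio) used for the extracellular
# protein-binding term of the partition model.
tissue,f_ew,f_iw,f_nl,f_np,ap_mg_g,ph_iw,albumin_ratio
adipose,0.135,0.017,0.8450,0.0016,0.40,7.0,0.049
bone,0.100,0.346,0.0174,0.0016,0.67,7.0,0.100
brain,0.162,0.620,0.0391,0.0015,0.40,7.0,0.048
gut,0.282,0.475,0.0487,0.0163,2.41,7.0,0.158
heart,0.320,0.456,0.0115,0.0166,2.25,7.0,0.157
kidney,0.273,0.483,0.0207,0.0162,5.03,7.0,0.130
liver,0.161,0.573,0.0348,0.0252,4.56,7.0,0.086
lung,0.336,0.446,0.0022,0.0128,3.91,7.0,0.212
muscle,0.118,0.630,0.0238,0.0072,1.53,7.0,0.064
skin,0.382,0.291,0.0284,0.0111,1.32,7.0,0.277
spleen,0.207,0.579,0.0201,0.0198,3.18,7.0,0.097
pancreas,0.120,0.664,0.0403,0.0090,0.40,7.0,0.060
rest,0.150,0.600,0.0400,0.0100,1.50,7.0,0.100
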