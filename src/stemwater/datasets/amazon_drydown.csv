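specimen,group,theta_t,theta_d,theta_mean,theta_sd,cv_pct,water_deficit_pct,abs_water_loss,max_diurnal_discharge,wood_density,height,dbh,sapwood_depth
Astrocaryum vulgare,palm,0.673,0.436,0.532,0.089,16.7,35.2,0.237,0.058,0.63,20,0.22,
Oenocarpus distichus,palm,0.728,0.521,0.674,0.063,9.38,28.4,0.207,0.038,0.29,13,0.22,
Protium tenuifolium,dicot,0.459,0.367,0.397,0.025,6.41,20.1,0.092,0.028,0.54,,,
Vouacapoua americana,dicot,0.391,0.300,0.333,0.026,7.88,23.3,0.091,0.025,0.82,,,
Licania octandra,dicot,0.485,0.400,0.427,0.021,5.0,17.5,0.085,0.012,0.69,,,
Pouteria decorticans,dicot,0.366,0.306,0.326,0.018,5.6,16.4,0.060,0.016,0.75,,,
Pouteria decorticans,dicot,0.352,0.292,0.315,0.016,5.1,17.0,0.060,0.013,0.75,,,
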