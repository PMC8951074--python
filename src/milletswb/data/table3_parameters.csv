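parameter,agrigreen,kantana,kangara
k_par,0.43,0.40,0.42
k_s,0.31,0.28,0.30
rue,0.0019,0.0026,0.002
dwr,11.3,15.8,11.2
wue_grain,1.43,1.29,1.23
wue_biomass,4.83,9.16,4.69
sla,22.49,19.91,23.34
p,2.76,1.27,2.48
rd_max,1.00,1.00,1.00
h_max,2.87,4.22,2.80
t_max_rate,9,9,9
t_base,10,10,10
t_opt,33,33,33
t_cutoff,45,45,45
gdd_emerge,60,64,60
gdd_flower,900,1058,832
gdd_maturity,1686,2124,1480
gdd_transition,670,780,655
dm_at_emergence,0.0019,0.0019,0.0019
stress_threshold,0.30,0.30,0.30
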