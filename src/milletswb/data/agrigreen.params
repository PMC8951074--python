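# Agrigreen: high-yielding hybrid pearl millet (determinate growth habit,
# grown mainly as fodder). Measured growth parameters.
name = agrigreen
rue = 0.0019
dwr = 11.3
k_par = 0.43
a_p = 0.8
a_n = 0.2
sla = 22.49
p = 2.76
rd_max = 1.00
h_max = 2.87
t_max_rate = 9
t_base = 10
t_opt = 33
t_cutoff = 45
gdd_emerge = 60
gdd_transition = 670
gdd_flower = 900
gdd_maturity = 1686
dm_at_emergence = 0.0019
stress_threshold = 0.30
root_fraction_initial = 0.25
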