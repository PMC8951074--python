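# Kangara: improved open-pollinated pearl millet (early maturing),
# released in Namibia in 1998. Measured growth parameters.
name = kangara
rue = 0.002
dwr = 11.2
k_par = 0.42
a_p = 0.8
a_n = 0.2
sla = 23.34
p = 2.48
rd_max = 1.00
h_max = 2.80
t_max_rate = 9
t_base = 10
t_opt = 33
t_cutoff = 45
gdd_emerge = 60
gdd_transition = 655
gdd_flower = 832
gdd_maturity = 1480
dm_at_emergence = 0.0019
stress_threshold = 0.30
root_fraction_initial = 0.25
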