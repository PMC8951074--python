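# Kantana: open-pollinated landrace pearl millet (late maturing, tall,
# indeterminate). Measured growth parameters; k_s is derived from k_par.
name = kantana
rue = 0.0026
dwr = 15.8
k_par = 0.40
a_p = 0.8
a_n = 0.2
sla = 19.91
p = 1.27
rd_max = 1.00
h_max = 4.22
t_max_rate = 9
t_base = 10
t_opt = 33
t_cutoff = 45
gdd_emerge = 64
gdd_transition = 780
gdd_flower = 1058
gdd_maturity = 2124
dm_at_emergence = 0.0019
stress_threshold = 0.30
root_fraction_initial = 0.25
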