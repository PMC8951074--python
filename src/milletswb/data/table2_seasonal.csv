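variety,P,I,ET,D,R,ETo,avg_vpd_kpa
kantana,542,405,670,179,0,436,0.78
kangara,542,437,598,144,0,412,0.83
agrigreen,542,458,653,134,0,425,0.81
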