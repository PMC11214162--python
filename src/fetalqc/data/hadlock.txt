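# Hadlock four-parameter gestational-age estimation formula.
# GA weeks = 10.85 + 0.060*HC*FL + 0.670*BPD + 0.168*AC, inputs in cm.
name = hadlock
transform = linear_ga_polynomial
measurement_unit = cm
ga_unit = weeks
required_inputs = bpd hc ac fl
ga_valid_range_days = 98 294
coef intercept = 10.85
coef hc*fl = 0.060
coef bpd = 0.670
coef ac = 0.168
range bpd = 1.5 11.0
range hc = 7.0 37.0
range ac = 5.0 45.0
range fl = 0.8 9.0
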