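# Intergrowth-21st late-pregnancy gestational-age estimation formula.
# ln(GA days) = 3.813 + 0.03243*(ln HC)^2 + 0.001644*FL*ln(HC), HC and FL in mm.
name = intergrowth21
transform = log_ga_polynomial
measurement_unit = mm
ga_unit = days
required_inputs = hc fl
ga_valid_range_days = 98 294
coef intercept = 3.813
coef log(hc)^2 = 0.03243
coef fl*log(hc) = 0.001644
range hc = 70 370
range fl = 8 90
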