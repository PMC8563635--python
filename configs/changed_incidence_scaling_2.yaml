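# Sensitivity scenario: incidence in every adult band scaled at 0.5
# relative to childhood (as published).
name: changed incidence scaling 2
ratio_set: [1.00, 0.50, 0.50, 0.50]
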