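# Sensitivity scenario: the child-mortality penalty is not applied, i.e.
# every country gets the optimal-care durations. Incident counts unchanged.
name: ignoring penalty function
override_penalty: 0.0
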