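# Sensitivity scenario: all maximum mean durations shrunk by a common factor
# while penalty and incidence ratios stay at core values.
# NON-CANONICAL placeholder multiplier: the originally used values are not
# published in accessible form; edit to taste.
name: reduced mean duration
duration_scale: 0.72
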