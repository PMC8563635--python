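# Sensitivity scenario: adult incidence ratios reduced below the core
# 0.50/0.30/0.25 set. NON-CANONICAL placeholder ratios: the originally used
# values are not published in accessible form; edit to taste.
name: changed incidence scaling 1
ratio_set: [1.00, 0.35, 0.20, 0.15]
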