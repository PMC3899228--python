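model,term,coefficient,printed_rate_ratio
porpoise,sea_state_1,-0.58,0.56
porpoise,sea_state_2,-1.69,0.18
rissos,site_B,2.3,9.99
rissos,site_C1,3.6,36.6
rissos,site_C2,2.2,9.02
rissos,sea_state_1,0.65,1.91
rissos,sea_state_2,-0.67,0.51
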