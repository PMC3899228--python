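term,cvll,delta_cvll,retained
Site,-3036.86,,True
Sea State,-2953.44,83.42,True
s(SD of current speed),-2906.52,46.92,True
s(Hour of day),-2872.70,33.82,True
s(Slope),-2855.48,17.22,True
s(Depth),-2843.52,11.96,True
s(Tidal stratification),-2834.70,8.83,True
s(Aspect),-2824.53,10.16,True
s(SD of slope),-2840.46,-15.92,False
s(Current direction),-2861.82,-21.36,False
s(Mean stratification),-2892.66,-30.84,False
s(Tidal state),-2927.68,-35.02,False
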