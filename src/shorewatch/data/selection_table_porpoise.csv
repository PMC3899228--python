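term,cvll,delta_cvll,retained
Sea State,-9645.54,,True
te(X Y),-9524.84,120.70,True
Site,-9421.26,103.58,True
s(Lunar cycle),-9336.61,84.65,True
s(Mean stratification),-9305.75,30.86,True
s(Day of year),-9285.25,20.50,True
s(Depth),-9267.39,17.85,True
s(Aspect),-9252.76,14.64,True
s(Tidal state),-9241.04,11.72,True
s(Slope),-9240.30,0.74,True
s(Year),-9241.38,-1.08,False
s(Hour of day),-9249.61,-8.23,False
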