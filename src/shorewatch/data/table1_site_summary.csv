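site,height_m,sector,scans,porpoise_sightings,porpoise_animals,rissos_sightings,rissos_animals,scans_july,scans_august,scans_september
A,17,110,900,62,104,0,0,155,531,214
B,17,2x90,887,16,28,33,57,107,475,305
C-1,37.5,110,805,28,63,174,242,124,300,381
C-2,37.5,90,1486,180,371,22,68,262,601,623
D,60,115,4183,505,856,9,33,1227,2037,919
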