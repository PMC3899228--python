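column,printed_total
scans,8261
porpoise_sightings,791
porpoise_animals,1422
rissos_sightings,238
rissos_animals,400
scans_july,1875
scans_august,3944
scans_september,2442
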