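label,contour_area_km2,survey_area_km2,printed_percent
porpoise_east,2.8,14.6,19
porpoise_sound,0.9,14.6,6
rissos_west,2.6,34.31,8
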