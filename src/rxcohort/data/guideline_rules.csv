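ruleset,atc_code,min_age,max_age,max_start_ddd,maint_low_ddd,maint_high_ddd
dutch_lenient,N06AB03,6,17,0.25,0.25,1.0
dutch_lenient,N06AB04,6,17,0.25,0.25,1.0
dutch_lenient,N06AB08,6,17,0.25,0.25,1.0
dutch_lenient,N06AB06,6,12,0.5,0.5,1.0
dutch_lenient,N06AB06,13,17,1.0,1.0,1.0
dutch_strict,N06AB03,6,17,0.25,0.25,1.0
dutch_strict,N06AB04,6,17,0.25,0.25,1.0
dutch_strict,N06AB08,6,17,0.25,0.25,1.0
dutch_strict,N06AB06,6,17,0.5,0.5,1.0
uk,N06AB03,6,17,0.5,0.5,1.0
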