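group,sgle_years,sgld_years
IHD,0.605,-0.292
treatable_preventable,0.173,-0.098
preventable,1.666,-1.021
treatable,0.083,-0.059
non_avoidable,1.268,-0.398
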