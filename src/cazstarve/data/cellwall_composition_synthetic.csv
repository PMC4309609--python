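strain,time_h,replicate,glucosamine,galactose,glucose,mannose
wt,0,1,13,8,73,6
wt,140,1,24,8,63,5
flbA,0,1,24,9,61,6
brlA,0,1,22,8,64,6
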