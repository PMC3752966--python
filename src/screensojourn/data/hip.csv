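stratum,start,end,cases,py
control,0,5,285,152406.417112
screen,,,55,20146.5201465
interval,0,1,13,21311.4754098
interval,1,2,7,6796.11650485
interval,2,3,1,3225.80645161
interval,3,4,3,2586.20689655
interval,4,5,5,2222.22222222
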