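stratum,start,end,cases,py
control,0,1,57,16904.3092522
control,1,2,63,16904.3092522
control,2,3,69,16904.3092522
control,3,4,75,16904.3092522
control,4,5,80,16904.3092522
control,5,6,86,16904.3092522
control,6,7,92,16904.3092522
control,7,8,98,16904.3092522
control,8,9,103,16904.3092522
control,9,10,109,16904.3092522
control,10,11,115,16904.3092522
control,11,12,120,16904.3092522
screen,,,1078,19962.962963
interval,0,1,17,18888.8888889
interval,1,2,10,18518.5185185
interval,2,3,24,18320.610687
interval,3,4,24,17910.4477612
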