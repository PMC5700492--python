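regimen_id,pre_pct,post_pct
FCR,10,7
BOR,2,2
RCHOP,17,0
BDR,6,5
DRC,24,21
BR,41,35
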