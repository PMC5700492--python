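drug,unit_mg,unit_cost_eur
ibrutinib,140,67.40
bendamustine,25,46.41
bortezomib,3.5,1300.00
cyclophosphamide,500,6.74
dexamethasone,4,0.86
doxorubicin,50,37.91
fludarabine,25,76.74
prednisone,5,0.09
rituximab,100,277.60
vincristine,1,6.80
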