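atc_code,drug_name,mg_per_ddd
N06AA02,imipramine,100
N06AA04,clomipramine,100
N06AA09,amitriptyline,75
N06AA10,nortriptyline,75
N06AB03,fluoxetine,20
N06AB04,citalopram,20
N06AB05,paroxetine,20
N06AB06,sertraline,50
N06AB08,fluvoxamine,100
N06AB10,escitalopram,10
N06AX03,mianserin,60
N06AX05,trazodone,300
N06AX11,mirtazapine,30
N06AX16,venlafaxine,100
N06AX21,duloxetine,60
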