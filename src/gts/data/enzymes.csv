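name,recognition,cut_top,cut_bottom,panel_1nt,notes
MboII,GAAGA,13,12,1,Type IIS; 1-nt 3' overhang
HphI,GGTGA,13,12,1,Type IIS; 1-nt 3' overhang
BmrI,ACTGGG,11,10,1,Type IIS; 1-nt 3' overhang
BciVI,GTATCC,18,17,1,Type IIS; 1-nt 3' overhang
MnlI,CCTC,11,10,1,Type IIS; 1-nt 3' overhang; provisional fifth panel member
BsaI,GGTCTC,7,11,0,Type IIS; 4-nt 5' overhang (Golden Gate)
NotI,GCGGCCGC,2,6,0,4-nt 5' overhang
BamHI,GGATCC,1,5,0,4-nt 5' overhang
AatII,GACGTC,5,1,0,4-nt 3' overhang
SrfI,GCCCGGGC,4,4,0,blunt
I-CeuI,TAACTATAACGGTCCTAAG,18,14,0,homing endonuclease; 19-bp core; offsets approximate; 4-nt 3' overhang
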