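element,matrix,mpl_mg_L
Cu,wine,1
Zn,wine,5
Pb,wine,0.15
Cd,wine,0.01
Ni,wine,
Co,wine,
As,wine,0.2
Cr,wine,
Hg,wine,
Cu,must,10
Zn,must,10
Pb,must,0.5
Cd,must,0.01
Ni,must,
Co,must,
As,must,0.2
Cr,must,
Hg,must,
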