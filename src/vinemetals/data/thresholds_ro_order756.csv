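element,normal,alert_susceptible,alert_less_susceptible,intervention_susceptible,intervention_less_susceptible
Cu,20,100,250,200,500
Zn,100,300,700,600,1500
Pb,20,50,250,100,1000
Cd,1,3,5,5,10
Ni,20,75,200,150,500
Co,15,30,100,50,250
As,5,15,25,25,50
Cr,30,100,300,300,600
Hg,0.1,1,4,2,10
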