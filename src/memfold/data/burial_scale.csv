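residue,one_letter,delta_g_water_octanol_kcal_mol
Ala,A,0.5
Arg,R,1.81
Asn,N,0.85
Asp,D,3.64
Cys,C,-0.02
Gln,Q,0.77
Glu,E,3.63
Gly,G,1.15
His,H,0.11
Ile,I,-1.12
Leu,L,-1.25
Lys,K,2.8
Met,M,-0.67
Phe,F,-1.71
Pro,P,0.14
Ser,S,0.46
Thr,T,0.25
Trp,W,-2.09
Tyr,Y,-0.71
Val,V,-0.46
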