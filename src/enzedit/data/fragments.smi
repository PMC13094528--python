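*C
*CC
*CCC
*C(C)C
*C(C)(C)C
*CCCC
*C=C
*C#C
*O
*OC
*OCC
*CO
*CCO
*C=O
*C(C)=O
*C(=O)O
*C(=O)OC
*C(=O)OCC
*OC(C)=O
*OC=O
*C(N)=O
*C(=O)NC
*NC(C)=O
*N
*NC
*N(C)C
*CN
*CCN
*C#N
*F
*Cl
*Br
*I
*C(F)(F)F
*S
*SC
*CS
*S(C)(=O)=O
*c1ccccc1
*Cc1ccccc1
*Oc1ccccc1
*Nc1ccccc1
*c1ccncc1
*c1ccco1
*c1cccs1
*C1CC1
*C1CCC1
*C1CCCC1
*C1CCCCC1
*OP(=O)(O)O
*P(=O)(O)O
*OS(=O)(=O)O
*[N+](C)(C)C
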