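CCO
CCN
CCC(=O)O
CC(=O)OCC
CC(N)C(=O)O
NCCCCN
CC(C)CO
OCC(O)CO
CC(=O)NC
CCOC(C)=O
CC(O)C(=O)O
NC(=O)CCC(N)C(=O)O
CCCCO
CC(C)(C)O
OC(=O)CCC(=O)O
NCCO
CNC(=O)C
CCSCC
CC=CC(=O)O
OCc1ccccc1
Nc1ccccc1C(=O)O
Cc1ccc(O)cc1
COc1ccccc1
CC(=O)c1ccccc1
c1ccc(CCN)cc1
OC(=O)c1ccccc1O
CC(C)Cc1ccc(C)cc1
CSCCC(N)C(=O)O
OCC1CCCCC1
CC1CCCCC1O
NC1CCCCC1
O=C1CCCCC1
CC(=O)CC(C)=O
CC(Br)C(=O)O
ClCC(=O)O
CCC(Cl)CC
NC(CO)C(=O)O
CC(O)CN
CCOCC
CC(C)NCC(O)c1ccccc1
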