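# Synthetic 26-gene EMT-style regulatory network topology (signed adjacency).
# Entry (row i, column j) is +1 if gene j activates gene i, -1 if it inhibits
# it, 0 otherwise.  The topology encodes the canonical EMT circuitry: the
# TGFB -> SNAIL -> ZEB cascade, the mutually inhibitory SNAIL/miR-34 and
# ZEB/miR-200 loops, epithelial gatekeepers (GRHL2, OVOL2, KLF4, ESRP1) and
# marker genes (CDH1, CDH2, VIM, FN1, CLDN4, CRB3).  This file is an editable
# synthetic stand-in, not a published adjacency; tests treat it as an opaque
# fixture.
TGFB SNAI1 SNAI2 ZEB1 ZEB2 TWIST1 FOXC2 GSC KLF8 MIR34A MIR200A MIR200B MIR200C MIR141 MIR101 MIR30C CDH1 CDH2 VIM FN1 OVOL2 GRHL2 KLF4 ESRP1 CLDN4 CRB3
TGFB    1  0  0  0  0  0  0  0  0  0  0 -1  0 -1  0  0  0  0  0  0  0  0  0  0  0  0
SNAI1   1 -1  0  0  0  0  0  0  0 -1  0  0  0  0  0  0  0  0  0  0 -1  0 -1  0  0  0
SNAI2   0  1  0  0  0  1  0  0  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
ZEB1    1  1  0  0  0  1  0  0  0  0 -1 -1 -1 -1 -1  0  0  0  0  0 -1 -1 -1  0  0  0
ZEB2    1  1  0  0  0  0  0  0  0  0 -1 -1 -1  0  0  0  0  0  0  0  0  0  0  0  0  0
TWIST1  1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
FOXC2   0  1  0  0  0  1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
GSC     1  1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
KLF8    1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
MIR34A  0 -1  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
MIR200A 0 -1  0 -1 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
MIR200B 0 -1  0 -1 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
MIR200C 0 -1  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
MIR141  0  0  0 -1 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
MIR101  0  0  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
MIR30C  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
CDH1    0 -1 -1 -1 -1 -1  0  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  1  0  1  0  0
CDH2    0  1  0  1  0  1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
VIM     0  1  0  1  1  1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
FN1     0  1  0  1  0  0  1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
OVOL2   0  0  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  1  0  0  0  0
GRHL2   0  0  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  1  0  0  0  0  0
KLF4    0 -1  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
ESRP1   0 -1  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  1  0  0  0  0
CLDN4   0  0  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  1  0  0  0  0
CRB3    0 -1  0 -1  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
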