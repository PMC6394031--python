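# Default human imprinted-gene exclusion list (gene symbols, editable).
# Well-established imprinted loci; one symbol per line.
H19
IGF2
IGF2-AS
INS
KCNQ1
KCNQ1OT1
CDKN1C
PHLDA2
SLC22A18
OSBPL5
MEG3
MEG8
DLK1
RTL1
DIO3
SNRPN
SNURF
NDN
MAGEL2
MKRN3
UBE3A
ATP10A
PEG3
ZIM2
PEG10
SGCE
MEST
MESTIT1
GRB10
PLAGL1
HYMAI
GNAS
GNAS-AS1
NAP1L5
NNAT
BLCAP
L3MBTL1
ZNF331
ZDBF2
GPR1
KCNK9
OSBPL5
DGCR6
DGCR6L
RB1
TP73
WT1
DIRAS3
NAA60
FAM50B
ZNF597
TFPI2
AIM1
SLC22A2
SLC22A3
IGF2R
AXL
IMPACT
MIMT1
PEG13
KHDC3L
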