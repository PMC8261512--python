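gene	role
EGFR	oncogene
KRAS	oncogene
BRAF	oncogene
PIK3CA	oncogene
MET	oncogene
ERBB2	oncogene
ALK	oncogene
RET	oncogene
ROS1	oncogene
NRAS	oncogene
AKT1	oncogene
MAP2K1	oncogene
TP53	tumor_suppressor
RB1	tumor_suppressor
STK11	tumor_suppressor
KEAP1	tumor_suppressor
PTEN	tumor_suppressor
CDKN2A	tumor_suppressor
NF1	tumor_suppressor
SMARCA4	tumor_suppressor
ATM	tumor_suppressor
BRCA2	tumor_suppressor
ARID1A	tumor_suppressor
MUC16	other
LRP1B	other
FAT1	other
ZFHX3	other
SPTA1	other
USH2A	other
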