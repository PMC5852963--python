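# Curated proto-oncogenes with tumor-suppressor function (POTSF) and their
# functional class (TF = transcription factor, KINASE, OTHER).
gene_id	potsf_class
BRCA1	TF
CAMTA1	TF
CBFA2T3	TF
CDX2	TF
CREB3L1	TF
CREBBP	TF
DDB2	TF
DNMT1	TF
DNMT3A	TF
ETV6	TF
EZH2	TF
FOXA1	TF
FOXL2	TF
FOXO1	TF
FOXO3	TF
FOXO4	TF
FOXP1	TF
FUS	TF
IRF4	TF
KLF4	TF
KLF5	TF
NCOA4	TF
NOTCH1	TF
NOTCH2	TF
NOTCH3	TF
NPM1	TF
NR4A3	TF
PAX5	TF
PML	TF
PPARG	TF
RB1	TF
RUNX1	TF
SMAD4	TF
STAT3	TF
TCF3	TF
TCF7L2	TF
TP53	TF
TP63	TF
TRIM24	TF
WT	TF
ZBTB16	TF
BCR	KINASE
CHEK2	KINASE
EPHA1	KINASE
EPHA3	KINASE
EPHB4	KINASE
FLT3	KINASE
MAP2K4	KINASE
MAP3K4	KINASE
MST1R	KINASE
NTRK3	KINASE
PRKAR1A	KINASE
PRKCB	KINASE
SYK	KINASE
ARHGEF12	OTHER
BCL10	OTHER
BRCA2	OTHER
CBL	OTHER
CDC73	OTHER
CDH11	OTHER
CDKN1B	OTHER
DCC	OTHER
DDX3X	OTHER
DICER1	OTHER
FAS	OTHER
FAT1	OTHER
GPC3	OTHER
IDH1	OTHER
IKZF2	OTHER
LIFR	OTHER
NF2	OTHER
NUP98	OTHER
PHF6	OTHER
PTPN1	OTHER
PTPN11	OTHER
RHOA	OTHER
RHOB	OTHER
SH2B3	OTHER
SLC9A3R1	OTHER
SOCS1	OTHER
SPOP	OTHER
SUZ12	OTHER
WHSC1L1	OTHER
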