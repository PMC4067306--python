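gene	OD	AS	GBM	pathways	annotation
ANGPT2	0	0	1	PI3K-Akt	Angiopoietin-2
CAV1	0	0	1	Focal Adh.	Caveolin
COL1A1	0	0	1	ECM;Focal Adh.;PI3K-Akt	Collagen alpha-1(I) chain
COL4A2	0	0	1	ECM;Focal Adh.;PI3K-Akt	Canstatin
COL5A2	0	0	1	ECM;Focal Adh.;PI3K-Akt	Collagen alpha-2(V) chain
FN1	0	0	1	ECM;Focal Adh.;PI3K-Akt	Ugl-Y3
LAMB1	0	0	1	ECM;Focal Adh.;PI3K-Akt	Laminin subunit beta-1
LAMC1	0	0	1	ECM;Focal Adh.;PI3K-Akt	Laminin subunit gamma-1
VEGFA	0	0	1	Focal Adh.;PI3K-Akt;VEGF	Vascular endothelial growth factor A
RELA	0	1	0	PI3K-Akt	Transcription factor p65
TGFB1	0	1	0	TGF-Beta	Transforming growth factor beta-1
CDK2	0	1	1	PI3K-Akt	Cyclin-dependent kinase 2
COL1A2	0	1	1	ECM;Focal Adh.;PI3K-Akt	Collagen alpha-2(I) chain
COL4A1	0	1	1	ECM;Focal Adh.;PI3K-Akt	Collagen alpha-1(IV) chain
LAMB2	0	1	1	ECM;Focal Adh.;PI3K-Akt	Laminin subunit gamma-1
TLR2	0	1	1	PI3K-Akt	Toll-like receptor 2
BMP7	1	0	0	TGF-Beta	Bone morphogenetic protein 7
NOG	1	0	0	TGF-Beta	Noggin
NOTCH1	1	0	0	Notch	Neurogenic locus notch homolog protein 1
PGF	1	0	0	Focal Adh.;PI3K-Akt	Placenta growth factor
RFC4	1	0	0	DNA Repair;Telomere	Replication factor C subunit 4
RFC5	1	0	0	DNA Repair;Telomere	Replication factor C subunit 5
RUVBL1	1	0	0	Telomere	RuvB-like 1
BMP2	1	1	0	TGF-Beta	Bone morphogenetic protein 2
CBLB	1	1	0	TGF-Beta	E3 ubiquitin-protein ligase CBL-B
DDIT4	1	1	0	PI3K-Akt	DNA damage-inducible transcript 4 protein
DLL3	1	1	0	Notch	Delta-like protein 3
E2F5	1	1	0	TGF-Beta	Transcription factor E2F5
ID1	1	1	0	TGF-Beta	DNA-binding protein inhibitor ID-1
ID4	1	1	0	TGF-Beta	DNA-binding protein inhibitor ID-4
MAML2	1	1	0	Notch	Mastermind-like protein 2
CD44	1	1	1	ECM	CD44 antigen
CDK4	1	1	1	PI3K-Akt	Highly similar to Cell division protein kinase 4
COL3A1	1	1	1	ECM;Focal Adh.;PI3K-Akt	Collagen alpha-1(III) chain
DTX3L	1	1	1	Notch	E3 ubiquitin-protein ligase DTX3L
EIF4EBP1	1	1	1	PI3K-Akt;TGF-Beta	Euk. transl. initiation factor 4E-binding protein 1
F2R	1	1	1	PI3K-Akt	Proteinase-activated receptor 1
ID3	1	1	1	TGF-Beta	DNA-binding protein inhibitor ID-3
MYC	1	1	1	PI3K-Akt;TGF-Beta	Myc proto-oncogene protein
TNC	1	1	1	ECM;Focal Adh.;PI3K-Akt	Tenascin
TP53	1	1	1	PI3K-Akt	Cellular tumor antigen p53
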