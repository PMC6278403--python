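sequence	activity	ref_id	source
GP	DPP-IV inhibitor	F0001	curated dipeptide set
AP	DPP-IV inhibitor	F0002	curated dipeptide set
VP	DPP-IV inhibitor	F0003	curated dipeptide set
IP	DPP-IV inhibitor	F0004	curated dipeptide set
LP	DPP-IV inhibitor	F0005	curated dipeptide set
SP	DPP-IV inhibitor	F0006	curated dipeptide set
KP	DPP-IV inhibitor	F0007	curated dipeptide set
MP	DPP-IV inhibitor	F0008	curated dipeptide set
WP	DPP-IV inhibitor	F0009	curated dipeptide set
YP	DPP-IV inhibitor	F0010	curated dipeptide set
TP	DPP-IV inhibitor	F0011	curated dipeptide set
FP	DPP-IV inhibitor	F0012	curated dipeptide set
HP	DPP-IV inhibitor	F0013	curated dipeptide set
RP	DPP-IV inhibitor	F0014	curated dipeptide set
EP	DPP-IV inhibitor	F0015	curated dipeptide set
NP	DPP-IV inhibitor	F0016	curated dipeptide set
QP	DPP-IV inhibitor	F0017	curated dipeptide set
DP	DPP-IV inhibitor	F0018	curated dipeptide set
VA	DPP-IV inhibitor	F0019	curated dipeptide set
WV	DPP-IV inhibitor	F0020	curated dipeptide set
WR	DPP-IV inhibitor	F0021	curated dipeptide set
PG	DPP-IV inhibitor	F0022	curated dipeptide set
PA	DPP-IV inhibitor	F0023	curated dipeptide set
PP	DPP-IV inhibitor	F0024	curated dipeptide set
KA	DPP-IV inhibitor	F0025	curated dipeptide set
KF	DPP-IV inhibitor	F0026	curated dipeptide set
IPI	DPP-IV inhibitor	F0027	diprotin A
VPL	DPP-IV inhibitor	F0028	diprotin B
IPA	DPP-IV inhibitor	F0029	curated tripeptide set
LPL	DPP-IV inhibitor	F0030	curated tripeptide set
APA	DPP-IV inhibitor	F0031	curated tripeptide set
GPA	DPP-IV inhibitor	F0032	curated tripeptide set
VY	ACE inhibitor	F0033	curated dipeptide set
IY	ACE inhibitor	F0034	curated dipeptide set
AY	ACE inhibitor	F0035	curated dipeptide set
GY	ACE inhibitor	F0036	curated dipeptide set
RY	ACE inhibitor	F0037	curated dipeptide set
KY	ACE inhibitor	F0038	curated dipeptide set
IW	ACE inhibitor	F0039	curated dipeptide set
VW	ACE inhibitor	F0040	curated dipeptide set
AW	ACE inhibitor	F0041	curated dipeptide set
LW	ACE inhibitor	F0042	curated dipeptide set
KW	ACE inhibitor	F0043	curated dipeptide set
FY	ACE inhibitor	F0044	curated dipeptide set
AF	ACE inhibitor	F0045	curated dipeptide set
GF	ACE inhibitor	F0046	curated dipeptide set
YP	ACE inhibitor	F0047	curated dipeptide set
GP	ACE inhibitor	F0048	curated dipeptide set
AP	ACE inhibitor	F0049	curated dipeptide set
IPP	ACE inhibitor	F0050	lactotripeptide
VPP	ACE inhibitor	F0051	lactotripeptide
IPP	antihypertensive	F0052	lactotripeptide
VPP	antihypertensive	F0053	lactotripeptide
VAP	ACE inhibitor	F0054	curated tripeptide set
LKP	ACE inhibitor	F0055	curated tripeptide set
IKW	ACE inhibitor	F0056	curated tripeptide set
FQP	ACE inhibitor	F0057	curated tripeptide set
GPL	ACE inhibitor	F0058	curated tripeptide set
HH	antioxidative	F0059	curated dipeptide set
AH	antioxidative	F0060	curated dipeptide set
LH	antioxidative	F0061	curated dipeptide set
PW	antioxidative	F0062	curated dipeptide set
WY	antioxidative	F0063	curated dipeptide set
EL	antioxidative	F0064	curated dipeptide set
AY	antioxidative	F0065	curated dipeptide set
HLH	antioxidative	F0066	curated tripeptide set
LHH	antioxidative	F0067	curated tripeptide set
KF	antihypertensive	F0068	multi-activity dipeptide
KF	hypotensive	F0069	multi-activity dipeptide
KF	other:inhibitor	F0070	multi-activity dipeptide
YG	hypotensive	F0071	curated dipeptide set
GQ	other:inhibitor	F0072	curated dipeptide set
EK	other:inhibitor	F0073	curated dipeptide set
LL	other:inhibitor	F0074	curated dipeptide set
GH	other:immunomodulating	F0075	curated dipeptide set
EW	other:immunomodulating	F0076	curated dipeptide set
QK	other:neuropeptide	F0077	curated dipeptide set
YGG	other:neuropeptide	F0078	curated tripeptide set
RF	other:neuropeptide	F0079	curated dipeptide set
VE	DPP-IV inhibitor	F0080	curated dipeptide set
ML	DPP-IV inhibitor	F0081	curated dipeptide set
HA	DPP-IV inhibitor	F0082	curated dipeptide set
FL	ACE inhibitor	F0083	curated dipeptide set
VF	ACE inhibitor	F0084	curated dipeptide set
YL	ACE inhibitor	F0085	curated dipeptide set
IR	ACE inhibitor	F0086	curated dipeptide set
AI	ACE inhibitor	F0087	curated dipeptide set
GL	ACE inhibitor	F0088	curated dipeptide set
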