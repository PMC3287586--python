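# Demo fixture: hand-encoded core of the trophectoderm / inner-cell-mass
# regulatory circuit of the mammalian preimplantation embryo (Hippo arm,
# Cdx2 switch, pluripotency triad). Evidence ids are synthetic demo tokens,
# not PubMed identifiers.
# source	subtype	target	evidence
LATS1	phosphorylation	YAP1	demo001
YAP1	activation	CDX2	demo002
TEAD4	activation	CDX2	demo002
TEAD4	activation	GATA3	demo003
CDX2	inhibition	NANOG	demo004
CDX2	inhibition	POU5F1	demo004
NANOG	inhibition	CDX2	demo005
POU5F1	inhibition	CDX2	demo006
NANOG	activation	POU5F1	demo007
POU5F1	activation	NANOG	demo007
SOX2	activation	NANOG	demo008
SOX2	activation	POU5F1	demo009
POU5F1	activation	POU5F1	demo009
NANOG	activation	NANOG	demo010
SOX2	activation	SOX2	demo010
TCF3	inhibition	POU5F1	demo011
TCF3	inhibition	NANOG	demo011
POU5F1	activation	FGF4	demo012
SOX2	activation	FGF4	demo012
SOX7	activation	GATA4	demo013
SOX7	activation	GATA6	demo013
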