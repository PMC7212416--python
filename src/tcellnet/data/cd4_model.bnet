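targets, factors
# Activation core (30 nodes): TCR/CD28 signaling, Ndrg1 anergy circuit,
# CTLA-4 checkpoint, AMPK/mTOR metabolic switch.
CD8086, CD8086
AMPK, AMPK
TCR, TCR & !CTLA4dim
CD28, CD8086 & !CTLA4dim
CD25, IL2G & !CTLA4dim
IL2G, NFAT & AP1 & !NDRG1
MTOR, CD25 | AKT
CTLA4, ZAP70 & IL2G
CTLA4dim, CTLA4 & !CD8086
NDRG1, NFAT & !AKT
MTORC1, MTOR & !AMPK
MTORC2, MTOR & AMPK
AP1, RASGTPR
STAT5, CD25 & !CTLA4dim
NFAT, Ca | (Ca & AKT)
NFKB, PKCT | (PKCT & PDK1)
AKT, (CD28 & !CTLA4dim) | PDK1
BCL2, AKT
DAG, PLC | (PLC & AKT)
SOS, CD28 | (CD28 & CD25)
RASGTPR, LAT & SOS & DAG
PDK1, CD25 | CD28
LCK, TCR & !CTLA4dim
ZAP70, TCR & LCK & !CTLA4dim
LAT, ZAP70
PLC, ZAP70
PIP2, PLC
IP3, PIP2
Ca, IP3
PKCT, DAG
# Differentiation modules: exogenous cytokines drive lineage transcription
# factors and endogenous cytokine output (Th1, Th2, Treg, Th17).
IL12e, IL12e
IFNGe, IFNGe
TBET, MTORC1 & NFKB & NFAT & AP1 & IL12e & IFNGe
IFNG, TBET & AP1 & NFAT
IL4e, IL4e
GATA3, MTORC2 & STAT5 & NFAT & IL4e
IL4, GATA3
TGFBe, TGFBe
IL10e, IL10e
FOXP3, (AMPK & NFAT & STAT5 & AP1 & IL2G & TGFBe & IL10e) | (IL10 & TGFBe & IL10e & CTLA4) | (TGFB & TGFBe)
IL10, FOXP3 & TGFBe
TGFB, FOXP3
IL21e, IL21e
RORGT, CD28 & MTORC1 & IL12e & TGFBe
IL21, IL21e | RORGT
IL17, RORGT
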