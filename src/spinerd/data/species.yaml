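# Chemical species of the CA1 dendrite+spine signaling model.
#
# D: diffusion constant in um^2/s (0 = non-diffusing / anchored).
# composition: elementary moieties contained in the species, used for
#   conservation accounting (e.g. PKAcAMP4 holds 1 regulatory dimer,
#   2 catalytic subunits, and 4 adenine nucleotides).
# tags: phosphorylation marks carried by the species.
# clamped: constant-count reservoir species (effectively infinite pools).
#
# "Da" is extracellular-derived dopamine (the tables' ligand L); Da_ext is
# the clamped exterior pool.

- {name: Da,        D: 111.3, composition: {Da: 1}}
- {name: Da_ext,    D: 0, clamped: true, composition: {Da: 1}}
- {name: R,         D: 0, composition: {R: 1}}
- {name: DaR,       D: 0, composition: {Da: 1, R: 1}}
- {name: Gabg,      D: 0, composition: {Ga: 1, Gbg: 1}}
- {name: DaRGabg,   D: 0, composition: {Da: 1, R: 1, Ga: 1, Gbg: 1}}
- {name: GabgR,     D: 0, composition: {R: 1, Ga: 1, Gbg: 1}}
- {name: DaRGbg,    D: 0, composition: {Da: 1, R: 1, Gbg: 1}}
- {name: Gbg,       D: 0, composition: {Gbg: 1}}
- {name: GaGTP,     D: 0, composition: {Ga: 1}}
- {name: GaGDP,     D: 0, composition: {Ga: 1}}
- {name: AC1,       D: 0, composition: {AC1: 1}}
- {name: AC1GaGTP,  D: 0, composition: {AC1: 1, Ga: 1}}
- {name: AC1GaGTPCaMCa4,    D: 0, composition: {AC1: 1, Ga: 1, CaM: 1, Ca: 4}}
- {name: AC1GaGTPCaMCa4ATP, D: 0, composition: {AC1: 1, Ga: 1, CaM: 1, Ca: 4, ade: 1}}
- {name: AC1CaMCa4,    D: 0, composition: {AC1: 1, CaM: 1, Ca: 4}}
- {name: AC1CaMCa4ATP, D: 0, composition: {AC1: 1, CaM: 1, Ca: 4, ade: 1}}
- {name: AC8,          D: 0, composition: {AC8: 1}}
- {name: AC8CaMCa4,    D: 0, composition: {AC8: 1, CaM: 1, Ca: 4}}
- {name: AC8CaMCa4ATP, D: 0, composition: {AC8: 1, CaM: 1, Ca: 4, ade: 1}}
- {name: ATP,  D: 74.7, composition: {ade: 1}}
- {name: AMP,  D: 85.5, composition: {ade: 1}}
- {name: cAMP, D: 86.4, composition: {ade: 1}}
- {name: PKA,      D: 0, composition: {PKAreg: 1, PKAcat: 2}}
- {name: PKAcAMP2, D: 0, composition: {PKAreg: 1, PKAcat: 2, ade: 2}}
- {name: PKAcAMP4, D: 0, composition: {PKAreg: 1, PKAcat: 2, ade: 4}}
- {name: R2CcAMP4, D: 0, composition: {PKAreg: 1, PKAcat: 1, ade: 4}}
- {name: PKAr,     D: 0, composition: {PKAreg: 1, ade: 4}}
- {name: PKAc,     D: 8.1, composition: {PKAcat: 1}}
- {name: PDE1,            D: 0, composition: {PDE1: 1}}
- {name: PDE1CaMCa4,      D: 0, composition: {PDE1: 1, CaM: 1, Ca: 4}}
- {name: PDE1CaMCa4cAMP,  D: 0, composition: {PDE1: 1, CaM: 1, Ca: 4, ade: 1}}
- {name: PDE4B,           D: 0, composition: {PDE4B: 1}}
- {name: PDE4BcAMP,       D: 0, composition: {PDE4B: 1, ade: 1}}
- {name: PKAcPDE4B,       D: 0, composition: {PDE4B: 1, PKAcat: 1}}
- {name: pPDE4B,          D: 0, composition: {PDE4B: 1}, tags: [pPDE4]}
- {name: pPDE4BcAMP,      D: 0, composition: {PDE4B: 1, ade: 1}, tags: [pPDE4]}
- {name: PKAcPDE4BcAMP,   D: 0, composition: {PDE4B: 1, PKAcat: 1, ade: 1}}
- {name: PDE4D,           D: 0, composition: {PDE4D: 1}}
- {name: PDE4DcAMP,       D: 0, composition: {PDE4D: 1, ade: 1}}
- {name: PKAcPDE4D,       D: 0, composition: {PDE4D: 1, PKAcat: 1}}
- {name: pPDE4D,          D: 0, composition: {PDE4D: 1}, tags: [pPDE4]}
- {name: pPDE4DcAMP,      D: 0, composition: {PDE4D: 1, ade: 1}, tags: [pPDE4]}
- {name: PKAcPDE4DcAMP,   D: 0, composition: {PDE4D: 1, PKAcat: 1, ade: 1}}
- {name: PKAcAMP4PDE4B,   D: 0, composition: {PKAreg: 1, PKAcat: 2, ade: 4, PDE4B: 1}}
- {name: PKAcAMP4PDE4D,   D: 0, composition: {PKAreg: 1, PKAcat: 2, ade: 4, PDE4D: 1}}
- {name: Ca,       D: 0, composition: {Ca: 1}}
- {name: Ca_ext,   D: 0, clamped: true, composition: {Ca: 1}}
- {name: CaM,      D: 11, composition: {CaM: 1}}
- {name: CaMCa2,   D: 11, composition: {CaM: 1, Ca: 2}}
- {name: CaMCa4,   D: 11, composition: {CaM: 1, Ca: 4}}
- {name: PP2B,        D: 0, composition: {PP2B: 1}}
- {name: PP2BCaM,     D: 0, composition: {PP2B: 1, CaM: 1}}
- {name: PP2BCaMCa2,  D: 0, composition: {PP2B: 1, CaM: 1, Ca: 2}}
- {name: PP2BCaMCa4,  D: 0, composition: {PP2B: 1, CaM: 1, Ca: 4}}
- {name: CaMKII,         D: 0, composition: {CaMKII: 1}}
- {name: CaMKIICaMCa4,   D: 3.6, composition: {CaMKII: 1, CaM: 1, Ca: 4}}
- {name: Complex,        D: 0, composition: {CaMKII: 2, CaM: 2, Ca: 8}}
- {name: pCaMKIICaMCa4,  D: 3.6, composition: {CaMKII: 1, CaM: 1, Ca: 4}, tags: [pCaMKII]}
- {name: pComplex,       D: 0, composition: {CaMKII: 2, CaM: 2, Ca: 8}, tags: [pCaMKII]}
- {name: pCaMKII,        D: 3.6, composition: {CaMKII: 1}, tags: [pCaMKII]}
- {name: PP1,               D: 0, composition: {PP1: 1}}
- {name: pCaMKIIPP1,        D: 0, composition: {CaMKII: 1, PP1: 1}, tags: [pCaMKII]}
- {name: pCaMKIICaMCa4PP1,  D: 0, composition: {CaMKII: 1, CaM: 1, Ca: 4, PP1: 1}, tags: [pCaMKII]}
- {name: I1,         D: 10.6, composition: {I1: 1}}
- {name: I1PKAc,     D: 10.6, composition: {I1: 1, PKAcat: 1}}
- {name: Ip35,       D: 10.6, composition: {I1: 1}, tags: [pI1]}
- {name: I1PKAcAMP4, D: 0, composition: {I1: 1, PKAreg: 1, PKAcat: 2, ade: 4}}
- {name: Ip35PP1,    D: 0, composition: {I1: 1, PP1: 1}, tags: [pI1]}
- {name: Ip35PP2B,   D: 0, composition: {I1: 1, PP2B: 1}, tags: [pI1]}
- {name: Ip35PP1PP2B, D: 0, composition: {I1: 1, PP1: 1, PP2B: 1}, tags: [pI1]}
- {name: PP1PP2B,    D: 0, composition: {PP1: 1, PP2B: 1}}
- {name: GluR1,               D: 0, composition: {GluR1: 1}}
- {name: GluR1_PKAc,          D: 0, composition: {GluR1: 1, PKAcat: 1}}
- {name: pS845GluR1,          D: 0, composition: {GluR1: 1}, tags: [pS845]}
- {name: GluR1_PKAcAMP4,      D: 0, composition: {GluR1: 1, PKAreg: 1, PKAcat: 2, ade: 4}}
- {name: GluR1_CaMKIICaMCa4,  D: 0, composition: {GluR1: 1, CaMKII: 1, CaM: 1, Ca: 4}}
- {name: pS831GluR1,          D: 0, composition: {GluR1: 1}, tags: [pS831]}
- {name: GluR1_pCaMKIICaMCa4, D: 0, composition: {GluR1: 1, CaMKII: 1, CaM: 1, Ca: 4}, tags: [pCaMKII]}
- {name: GluR1_pCaMKII,       D: 0, composition: {GluR1: 1, CaMKII: 1}, tags: [pCaMKII]}
- {name: pS845GluR1_CaMKIICaMCa4,  D: 0, composition: {GluR1: 1, CaMKII: 1, CaM: 1, Ca: 4}, tags: [pS845]}
- {name: pS845pS831GluR1,          D: 0, composition: {GluR1: 1}, tags: [pS845, pS831]}
- {name: pS845GluR1_pCaMKIICaMCa4, D: 0, composition: {GluR1: 1, CaMKII: 1, CaM: 1, Ca: 4}, tags: [pS845, pCaMKII]}
- {name: pS845GluR1_pCaMKII,       D: 0, composition: {GluR1: 1, CaMKII: 1}, tags: [pS845, pCaMKII]}
- {name: pS831GluR1_PKAc,          D: 0, composition: {GluR1: 1, PKAcat: 1}, tags: [pS831]}
- {name: pS831GluR1_PKAcAMP4,      D: 0, composition: {GluR1: 1, PKAreg: 1, PKAcat: 2, ade: 4}, tags: [pS831]}
- {name: pS845GluR1_PP1,           D: 0, composition: {GluR1: 1, PP1: 1}, tags: [pS845]}
- {name: pS845pS831GluR1_PP1,      D: 0, composition: {GluR1: 1, PP1: 1}, tags: [pS845, pS831]}
- {name: pS831GluR1_PP1,           D: 0, composition: {GluR1: 1, PP1: 1}, tags: [pS831]}
- {name: pS845GluR1_PP2B,          D: 0, composition: {GluR1: 1, PP2B: 1, CaM: 1, Ca: 4}, tags: [pS845]}
- {name: pmca,   D: 0, composition: {pmca: 1}}
- {name: pmcaCa, D: 0, composition: {pmca: 1, Ca: 1}}
- {name: ncx,    D: 0, composition: {ncx: 1}}
- {name: ncxCa,  D: 0, composition: {ncx: 1, Ca: 1}}
- {name: Calbindin,   D: 9.3, composition: {Calbindin: 1}}
- {name: CalbindinCa, D: 9.3, composition: {Calbindin: 1, Ca: 1}}
- {name: CaB,   D: 10, composition: {CaB: 1}}
- {name: CaBCa, D: 10, composition: {CaB: 1, Ca: 1}}
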