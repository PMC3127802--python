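"""Frozen printed constants used as a double-entry transcription check
against the shipped model files: every reaction row (kf, kb, kcat), every
basal concentration, and every diffusion constant."""

# (equation, kf, kb, kcat); None where the table prints nothing
REACTION_ROWS = [
    # cAMP signaling
    ("Da + R <-> DaR", 0.0011111, 10, None),
    ("DaR + Gabg <-> DaRGabg -> DaRGbg + GaGTP", 6.0e-4, 0.001, 20),
    ("Gabg + R <-> GabgR", 6.0e-5, 3.0e-4, None),
    ("GabgR + Da <-> DaRGabg -> DaRGbg + GaGTP", 0.0033333, 10, 20),
    ("DaRGbg -> DaR + Gbg", 80, None, None),
    ("GaGTP -> GaGDP", 10, None, None),
    ("GaGDP + Gbg -> Gabg", 100, None, None),
    ("GaGTP + AC1 <-> AC1GaGTP", 0.0385, 10, None),
    ("AC1GaGTP + CaMCa4 <-> AC1GaGTPCaMCa4", 0.012, 0.9, None),
    ("AC1GaGTPCaMCa4 + ATP <-> AC1GaGTPCaMCa4ATP -> AC1GaGTPCaMCa4 + cAMP",
     0.01, 2273, 28.42),
    ("AC1 + CaMCa4 <-> AC1CaMCa4", 0.006, 0.9, None),
    ("AC1CaMCa4 + ATP <-> AC1CaMCa4ATP -> AC1CaMCa4 + cAMP", 0.01, 2273, 2.843),
    ("AC8 + CaMCa4 <-> AC8CaMCa4", 0.00125, 1, None),
    ("AC8CaMCa4 + ATP <-> AC8CaMCa4ATP -> AC8CaMCa4 + cAMP", 0.01, 2273, 2.843),
    ("PKA + 2 cAMP <-> PKAcAMP2", 8.70e-5, 0.02, None),
    ("PKAcAMP2 + 2 cAMP <-> PKAcAMP4", 1.15e-4, 0.2, None),
    ("PKAcAMP4 <-> R2CcAMP4 + PKAc", 0.038, 0.016, None),
    ("R2CcAMP4 <-> PKAr + PKAc", 0.152, 0.004, None),
    ("PDE1 + CaMCa4 <-> PDE1CaMCa4", 0.1, 1, None),
    ("PDE1CaMCa4 + cAMP <-> PDE1CaMCa4cAMP -> PDE1CaMCa4 + AMP", 0.0046, 44, 11),
    ("AMP -> ATP", 1, None, None),
    ("PDE4B + cAMP <-> PDE4BcAMP -> PDE4B + AMP", 0.03038, 77.78, 19.44),
    ("PKAc + PDE4B <-> PKAcPDE4B -> PKAc + pPDE4B", 0.00428, 5.6, 1.25),
    ("pPDE4B -> PDE4B", 0.25, None, None),
    ("pPDE4B + cAMP <-> pPDE4BcAMP -> pPDE4B + AMP", 0.03038, 77.78, 38.89),
    ("PDE4BcAMP + PKAc <-> PKAcPDE4BcAMP -> pPDE4BcAMP + PKAc", 0.00428, 5.6, 1.25),
    ("PDE4D + cAMP <-> PDE4DcAMP -> PDE4D + AMP", 0.01296, 60.14, 15.03),
    ("PKAc + PDE4D <-> PKAcPDE4D -> PKAc + pPDE4D", 0.00428, 5.6, 1.25),
    ("pPDE4D -> PDE4D", 0.25, None, None),
    ("pPDE4D + cAMP <-> pPDE4DcAMP -> pPDE4D + AMP", 0.01296, 60.14, 30.06),
    ("PDE4DcAMP + PKAc <-> PKAcPDE4DcAMP -> pPDE4DcAMP + PKAc", 0.00428, 5.6, 1.25),
    ("PKAcAMP4 + PDE4B <-> PKAcAMP4PDE4B", 6.25e-5, 5.44e-3, None),
    ("PKAcAMP4 + PDE4D <-> PKAcAMP4PDE4D", 6.25e-5, 5.44e-3, None),
    ("PKAcAMP4PDE4B <-> R2CcAMP4 + PKAcPDE4B", 0.38, 0.016, None),
    ("PKAcAMP4PDE4D <-> R2CcAMP4 + PKAcPDE4D", 0.38, 0.016, None),
    # calcium-activated pathways
    ("CaM + 2 Ca <-> CaMCa2", 0.006, 9.1, None),
    ("CaMCa2 + 2 Ca <-> CaMCa4", 0.1, 1000, None),
    ("CaM + PP2B <-> PP2BCaM", 0.0046, 0.0012, None),
    ("PP2BCaM + 2 Ca <-> PP2BCaMCa2", 0.006, 0.91, None),
    ("PP2BCaMCa2 + 2 Ca <-> PP2BCaMCa4", 0.1, 1000, None),
    ("CaMCa2 + PP2B <-> PP2BCaMCa2", 0.046, 0.0012, None),
    ("CaMCa4 + PP2B <-> PP2BCaMCa4", 0.046, 0.0012, None),
    ("CaMCa4 + CaMKII <-> CaMKIICaMCa4", 0.01, 3, None),
    ("CaMKIICaMCa4 + CaMKIICaMCa4 <-> Complex", 1.0e-4, 10, None),
    ("pCaMKIICaMCa4 + CaMKIICaMCa4 <-> pComplex", 1.0e-4, 10, None),
    ("pCaMKIICaMCa4 + Complex -> pCaMKIICaMCa4 + pComplex", 1.0e-4, None, None),
    ("CaMKIICaMCa4 + Complex -> CaMKIICaMCa4 + pComplex", 1.0e-4, None, None),
    ("Complex + Complex -> Complex + pComplex", 0.01, None, None),
    ("Complex + pComplex -> pComplex + pComplex", 0.03, None, None),
    ("pCaMKIICaMCa4 <-> CaMCa4 + pCaMKII", 8.0e-4, 0.01, None),
    ("pCaMKII + PP1 <-> pCaMKIIPP1 -> PP1 + CaMKII", 6.0e-7, 0.34, 0.086),
    ("pCaMKIICaMCa4 + PP1 <-> pCaMKIICaMCa4PP1 -> PP1 + CaMKIICaMCa4",
     6.0e-7, 0.34, 0.086),
    ("I1 + PKAc <-> I1PKAc -> Ip35 + PKAc", 0.0014, 5.6, 1.4),
    ("I1 + PKAcAMP4 <-> I1PKAcAMP4", 1.40e-4, 5.6, None),
    ("I1PKAcAMP4 <-> R2CcAMP4 + I1PKAc", 0.38, 0.016, None),
    ("Ip35 + PP1 <-> Ip35PP1", 0.001, 0.0011, None),
    ("Ip35 + PP2B <-> Ip35PP2B -> I1 + PP2B", 0.00233, 11.2, 2.8),
    ("Ip35PP1 + PP2B <-> Ip35PP1PP2B -> I1 + PP1PP2B", 0.00233, 11.2, 2.8),
    ("PP1PP2B -> PP1 + PP2B", None, None, 1.5),
    # AMPA receptor pathway
    ("GluR1 + PKAc <-> GluR1_PKAc -> pS845GluR1 + PKAc", 0.00402, 24, 6),
    ("PKAcAMP4 + GluR1 <-> GluR1_PKAcAMP4", 4.02e-4, 24, None),
    ("GluR1_PKAcAMP4 <-> R2CcAMP4 + GluR1_PKAc", 0.38, 0.016, None),
    ("GluR1 + CaMKIICaMCa4 <-> GluR1_CaMKIICaMCa4 -> pS831GluR1 + CaMKIICaMCa4",
     2.224e-5, 1.6, 0.4),
    ("GluR1 + pCaMKIICaMCa4 <-> GluR1_pCaMKIICaMCa4 -> pS831GluR1 + pCaMKIICaMCa4",
     2.780e-5, 2, 0.5),
    ("GluR1 + pCaMKII <-> GluR1_pCaMKII -> pS831GluR1 + pCaMKII",
     2.224e-5, 1.6, 0.4),
    ("pS845GluR1 + CaMKIICaMCa4 <-> pS845GluR1_CaMKIICaMCa4 -> pS845pS831GluR1 + CaMKIICaMCa4",
     2.224e-5, 1.6, 0.4),
    ("pS845GluR1 + pCaMKIICaMCa4 <-> pS845GluR1_pCaMKIICaMCa4 -> pS845pS831GluR1 + pCaMKIICaMCa4",
     2.780e-5, 2, 0.5),
    ("pS845GluR1 + pCaMKII <-> pS845GluR1_pCaMKII -> pS845pS831GluR1 + pCaMKII",
     2.224e-5, 1.6, 0.4),
    ("pS831GluR1 + PKAc <-> pS831GluR1_PKAc -> pS845pS831GluR1 + PKAc",
     0.004, 24, 6),
    ("PKAcAMP4 + pS831GluR1 <-> pS831GluR1_PKAcAMP4", 4.02e-4, 24, None),
    ("pS831GluR1_PKAcAMP4 <-> R2CcAMP4 + pS831GluR1_PKAc", 0.38, 0.016, None),
    ("pS845GluR1 + PP1 <-> pS845GluR1_PP1 -> GluR1 + PP1", 8.700e-4, 0.68, 0.17),
    ("pS845pS831GluR1 + PP1 <-> pS845pS831GluR1_PP1 -> pS831GluR1 + PP1",
     8.750e-4, 1.4, 0.35),
    ("pS831GluR1 + PP1 <-> pS831GluR1_PP1 -> GluR1 + PP1", 8.750e-4, 1.4, 0.35),
    ("pS845GluR1 + PP2BCaMCa4 <-> pS845GluR1_PP2B -> GluR1 + PP2BCaMCa4",
     0.00201, 8, 2),
    # calcium dynamics and dopamine
    ("Ca + pmca <-> pmcaCa -> pmca + Ca_ext", 0.05, 7, 3.5),
    ("Ca + ncx <-> ncxCa -> ncx + Ca_ext", 0.0168, 11.2, 5.6),
    ("Ca_ext -> Ca", 0.0017, None, None),
    ("Ca + Calbindin <-> CalbindinCa", 0.028, 19.6, None),
    ("Ca + CaB -> CaBCa", 0.028, None, None),
    ("Da <-> Da_ext", 2, 2.0e-5, None),
]

# basal concentrations, nM ("general cytosol")
INITIAL_NM = {
    "Ca": 51, "Ca_ext": 2015100, "Calbindin": 149590, "CalbindinCa": 11348,
    "Da": 10.379, "Da_ext": 1019100, "ATP": 1997200, "cAMP": 60,
    "PDE1": 3371, "PDE1CaMCa4": 574, "PDE1CaMCa4cAMP": 3, "AMP": 839,
    "CaM": 9126, "CaMCa2": 315, "CaMCa4": 2,
    "PP2BCaM": 2960, "PP2BCaMCa2": 1020, "PP2BCaMCa4": 6,
    "CaMKII": 19266, "CaMKIICaMCa4": 112, "pCaMKIICaMCa4": 598, "pCaMKII": 26,
    "I1": 530, "I1PKAc": 2, "Ip35": 6, "PP1": 587, "Ip35PP1": 884,
    "PDE4B": 902, "PDE4BcAMP": 24, "PKAcPDE4B": 9, "pPDE4B": 48,
    "PDE4D": 915, "PDE4DcAMP": 13, "PKAcPDE4D": 9, "pPDE4D": 45,
}

# diffusion constants, um^2/s; all unlisted species are 0
DIFFUSION = {
    "Calbindin": 9.3, "CalbindinCa": 9.3, "CaBCa": 10, "CaB": 10,
    "Da": 111.3, "ATP": 74.7, "AMP": 85.5, "cAMP": 86.4,
    "CaM": 11, "CaMCa2": 11, "CaMCa4": 11,
    "CaMKIICaMCa4": 3.6, "pCaMKIICaMCa4": 3.6, "pCaMKII": 3.6,
    "PKAc": 8.1, "I1": 10.6, "I1PKAc": 10.6, "Ip35": 10.6,
}
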