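# Initial concentrations (nM), "general cytosol": populated over the entire
# morphology.  Species not listed start at 0.  Ca_ext and Da_ext are clamped
# reservoir pools emulating a constant exterior concentration.
general_cytosol_nM:
  Ca: 51
  Ca_ext: 2015100
  Calbindin: 149590
  CalbindinCa: 11348
  Da: 10.379
  Da_ext: 1019100
  ATP: 1997200
  cAMP: 60
  PDE1: 3371
  PDE1CaMCa4: 574
  PDE1CaMCa4cAMP: 3
  AMP: 839
  CaM: 9126
  CaMCa2: 315
  CaMCa4: 2
  PP2BCaM: 2960
  PP2BCaMCa2: 1020
  PP2BCaMCa4: 6
  CaMKII: 19266
  CaMKIICaMCa4: 112
  pCaMKIICaMCa4: 598
  pCaMKII: 26
  I1: 530
  I1PKAc: 2
  Ip35: 6
  PP1: 587
  Ip35PP1: 884
  PDE4B: 902
  PDE4BcAMP: 24
  PKAcPDE4B: 9
  pPDE4B: 48
  PDE4D: 915
  PDE4DcAMP: 13
  PKAcPDE4D: 9
  pPDE4D: 45

# Quantities of the anchored species are not part of the concentration table
# above; they are placement-dependent config inputs.  All values below are
# ASSUMED defaults (see docs/methods.md): total molecule numbers for the
# receptor/G-protein/cyclase/kinase/receptor-target pools, and membrane
# surface densities (molecules per um^2) for the two calcium pumps.  The pump
# densities were chosen so that PMCA+NCX removal balances the Ca_ext leak at
# the basal calcium concentration of 51 nM.
anchored_molecules:
  R: 300
  Gabg: 900
  AC1: 2400
  AC8: 1200
  PKA: 2400
  GluR1: 80
pump_density_per_um2:
  pmca: 650
  ncx: 400
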