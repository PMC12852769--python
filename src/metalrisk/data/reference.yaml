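# Packaged reference bundle, version 1.
#
# Toxicological constants and exposure defaults for the dietary risk
# assessment of metal residues in small-ruminant muscle and liver.
# Units: rfd mg/kg-bw/day; csf per (mg/kg-bw/day); mrl mg/kg tissue;
# lod_ppb instrument detection limits in ppb (ug/kg).
version: 1

elements:
  Cd: toxic
  Pb: toxic
  Ni: toxic
  Co: essential
  Se: essential
  Cu: essential
  Fe: essential
  Mg: essential
  Mn: essential
  Zn: essential

# Oral reference doses (USEPA). Mg has no established RfD and is
# excluded from hazard-quotient computation.
rfd:
  Cd: 0.001
  Ni: 0.02
  Co: 0.03
  Se: 0.005
  Pb: 0.004
  Cu: 0.04
  Fe: 0.7
  Mn: 0.14
  Zn: 0.3

# Oral cancer slope factors; available only for Pb, Cd, Ni.
csf:
  Pb: 0.0085
  Cd: 0.380
  Ni: 0.84

# Maximum residue levels by tissue, with issuing authority.
mrl:
  Cd: {muscle: 0.05, liver: 0.50, source: EC}
  Pb: {muscle: 0.10, liver: 0.50, source: Codex}
  Ni: {muscle: 0.5, liver: 0.5, source: WHO}
  Cu: {muscle: 40.0, liver: 40.0, source: Codex}
  Mn: {muscle: 3.99, liver: 0.5, source: FAO/WHO}
  Zn: {muscle: 50.0, liver: 80.0, source: FAO/WHO}

# ICP-OES limits of detection, ppb.
lod_ppb:
  Pb: 0.942
  Co: 0.160
  Cu: 0.904
  Se: 6.638
  Ni: 0.749
  Cd: 0.127
  Fe: 0.225
  Mg: 1.0007
  Mn: 0.036
  Zn: 0.173

# Adult ingestion scenario: 2 g/day liver, 3.14 kg/year meat, 70 kg body
# weight, daily exposure over a 70-year horizon (averaging time 25550 d).
exposure:
  ir_muscle_kg_per_year: 3.14
  ir_liver: 0.002
  bw: 70.0
  ef: 365
  ed: 70
  at: 25550
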