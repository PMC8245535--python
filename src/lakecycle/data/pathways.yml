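# Default carbon / nitrogen / sulfur reaction definitions.
#
# Each reaction is AND-of-OR-groups over HMM model ids: present iff every
# group has at least one qualifying gene copy.  Gene sets follow the marker
# conventions of METABOLIC-style annotation suites and are package defaults,
# meant to be edited per study; cutoffs are minimum bit scores (models not
# listed under `cutoffs` use default_cutoff).
default_cutoff: 50

reactions:
  # ---- carbon -------------------------------------------------------------
  - id: organic_carbon_oxidation
    cycle: carbon
    label: organic carbon oxidation
    substrate: "organic C (0 to -IV)"
    product: "CO2 (+IV)"
    logic: [[gapA, porA, adh]]
  - id: fermentation
    cycle: carbon
    label: fermentation
    substrate: "pyruvate (0)"
    product: "acetate/ethanol (-I)"
    logic: [[pflB, ldhA, adhE]]
  - id: hydrogen_generation
    cycle: carbon
    label: hydrogen generation
    substrate: "H+ (+I)"
    product: "H2 (0)"
    logic: [[hydA, hoxH]]
  - id: hydrogen_oxidation
    cycle: carbon
    label: hydrogen oxidation
    substrate: "H2 (0)"
    product: "H+ (+I)"
    logic: [[hyaB, hybC]]
  - id: methanogenesis
    cycle: carbon
    label: methanogenesis
    substrate: "CO2/acetate (+IV/0)"
    product: "CH4 (-IV)"
    logic: [[mcrA], [mcrB], [mcrG]]
  - id: methanotrophy
    cycle: carbon
    label: methanotrophy
    substrate: "CH4 (-IV)"
    product: "CH3OH (-II)"
    logic: [[pmoA, mmoX]]
    cutoffs: {pmoA: 80}
  - id: co2_fixation
    cycle: carbon
    label: CO2 fixation
    substrate: "CO2 (+IV)"
    product: "organic C (0)"
    logic: [[rbcL, aclB, acsB]]

  # ---- nitrogen -----------------------------------------------------------
  - id: nitrogen_fixation
    cycle: nitrogen
    label: nitrogen fixation
    substrate: "N2 (0)"
    product: "NH3 (-III)"
    logic: [[nifH], [nifD], [nifK]]
  - id: ammonia_oxidation
    cycle: nitrogen
    label: ammonia oxidation
    substrate: "NH3 (-III)"
    product: "NO2- (+III)"
    logic: [[amoA], [amoB]]
    cutoffs: {amoA: 80}
  - id: nitrite_oxidation
    cycle: nitrogen
    label: nitrite oxidation
    substrate: "NO2- (+III)"
    product: "NO3- (+V)"
    logic: [[nxrA], [nxrB]]
  - id: comammox
    cycle: nitrogen
    label: complete ammonia oxidation
    substrate: "NH3 (-III)"
    product: "NO3- (+V)"
    logic: [[amoA], [amoB], [nxrA], [nxrB]]
    cutoffs: {amoA: 80}
  - id: nitrate_reduction
    cycle: nitrogen
    label: nitrate reduction
    substrate: "NO3- (+V)"
    product: "NO2- (+III)"
    logic: [[narG, napA], [narH, napB]]
  - id: nitrite_reduction
    cycle: nitrogen
    label: nitrite reduction
    substrate: "NO2- (+III)"
    product: "NO (+II)"
    logic: [[nirK, nirS]]
  - id: nitric_oxide_reduction
    cycle: nitrogen
    label: nitric oxide reduction
    substrate: "NO (+II)"
    product: "N2O (+I)"
    logic: [[norB], [norC]]
  - id: nitrous_oxide_reduction
    cycle: nitrogen
    label: nitrous oxide reduction
    substrate: "N2O (+I)"
    product: "N2 (0)"
    logic: [[nosZ]]
  - id: dnra
    cycle: nitrogen
    label: nitrite ammonification (DNRA)
    substrate: "NO2- (+III)"
    product: "NH4+ (-III)"
    logic: [[nrfA, nirB]]
  - id: anammox
    cycle: nitrogen
    label: anaerobic ammonium oxidation
    substrate: "NH4+ + NO2- (-III/+III)"
    product: "N2 (0)"
    logic: [[hzsA], [hdh]]

  # ---- sulfur -------------------------------------------------------------
  - id: sulfide_oxidation
    cycle: sulfur
    label: sulfide oxidation
    substrate: "H2S (-II)"
    product: "S0 (0)"
    logic: [[sqr, fccB]]
  - id: sulfur_oxidation
    cycle: sulfur
    label: sulfur oxidation
    substrate: "S0 (0)"
    product: "SO3 2- (+IV)"
    logic: [[sdo, soxB]]
  - id: sulfite_oxidation
    cycle: sulfur
    label: sulfite oxidation
    substrate: "SO3 2- (+IV)"
    product: "SO4 2- (+VI)"
    logic: [[soeA, sorA]]
  - id: thiosulfate_oxidation
    cycle: sulfur
    label: thiosulfate oxidation
    substrate: "S2O3 2- (+II)"
    product: "SO4 2- (+VI)"
    logic: [[soxB], [soxC]]
  - id: sulfate_reduction
    cycle: sulfur
    label: sulfate reduction
    substrate: "SO4 2- (+VI)"
    product: "SO3 2- (+IV)"
    logic: [[sat], [aprA], [dsrA]]
  - id: sulfite_reduction
    cycle: sulfur
    label: sulfite reduction
    substrate: "SO3 2- (+IV)"
    product: "H2S (-II)"
    logic: [[dsrA], [dsrB]]
  - id: sulfur_reduction
    cycle: sulfur
    label: sulfur reduction
    substrate: "S0 (0)"
    product: "H2S (-II)"
    logic: [[sreA]]
  - id: thiosulfate_disproportionation
    cycle: sulfur
    label: thiosulfate disproportionation
    substrate: "S2O3 2- (+II)"
    product: "H2S + SO4 2- (-II/+VI)"
    logic: [[phsA]]
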