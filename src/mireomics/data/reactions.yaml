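# Reaction and route library for the catechin / phloroglucinol hydrogen ledger.
#
# Conventions
# -----------
# * Formulas use standard element symbols plus three bookkeeping moieties that
#   behave like elements: Nad (nicotinamide core of NAD+/NADH), Ndp (NADP+/
#   NADPH core), Fdx (ferredoxin). This keeps every cofactor couple exactly
#   element- and charge-balanced: NADH differs from NAD+ by one H atom and one
#   electron; reduced ferredoxin carries two electrons (charge -2) per unit.
# * Stoichiometric coefficients are signed rationals, negative = consumed.
# * Dehydroxylations of aromatic rings are 2-electron reductions releasing
#   water; the flavanone/flavanonol C-ring reduction (FCR) is a 2-electron
#   reduction; chalcone isomerase (CHI) and the hydrolytic cleavages (PHY and
#   the auronol cleavage) are redox-neutral.
# * The initial oxidation of catechin to taxifolin (C-4 CH2 -> C=O) is a
#   4-electron oxidation written against NAD+.
# * Phloroglucinol fermentation is shipped as a single lumped, carbon- and
#   electron-balanced reaction to acetate + butyrate; the NADPH input is the
#   phloroglucinol reductase (PGR) step and the reduced ferredoxin output is
#   the electron-bifurcating butyryl-CoA dehydrogenase step.

species:
  catechin:        {formula: C15H14O6, charge: 0, role: metabolite}
  taxifolin:       {formula: C15H12O7, charge: 0, role: metabolite}
  eriodictyol:     {formula: C15H12O6, charge: 0, role: metabolite}
  naringenin:      {formula: C15H12O5, charge: 0, role: metabolite}
  dihydrokaempferol: {formula: C15H12O6, charge: 0, role: metabolite}
  maesopsin:       {formula: C15H12O6, charge: 0, role: metabolite}
  phloretin:       {formula: C15H14O5, charge: 0, role: metabolite}
  # dihydrochalcone of eriodictyol: 3-(3,4-dihydroxyphenyl)-1-(2,4,6-trihydroxyphenyl)propan-1-one
  eriodictyol_dihydrochalcone: {formula: C15H14O6, charge: 0, role: metabolite}
  phloroglucinol:  {formula: C6H6O3, charge: 0, role: metabolite}
  hydroxyphenylpropionate_4: {formula: C9H10O3, charge: 0, role: metabolite}
  dihydroxyphenylpropionate_34: {formula: C9H10O4, charge: 0, role: metabolite}
  hydroxyphenylacetate_4: {formula: C8H8O3, charge: 0, role: metabolite}
  formate:         {formula: CH2O2, charge: 0, role: metabolite}
  acetate:         {formula: C2H4O2, charge: 0, role: metabolite}
  butyrate:        {formula: C4H8O2, charge: 0, role: metabolite}
  co2:             {formula: CO2, charge: 0, role: gas}
  ch4:             {formula: CH4, charge: 0, role: gas}
  h2:              {formula: H2, charge: 0, role: gas}
  h2o:             {formula: H2O, charge: 0, role: water}
  h_plus:          {formula: H, charge: 1, role: proton}
  nad_plus:        {formula: Nad, charge: 1, role: cofactor}
  nadh:            {formula: NadH, charge: 0, role: cofactor}
  nadp_plus:       {formula: Ndp, charge: 1, role: cofactor}
  nadph:           {formula: NdpH, charge: 0, role: cofactor}
  fd_ox:           {formula: Fdx, charge: 0, role: cofactor}
  fd_red:          {formula: Fdx, charge: -2, role: cofactor}

couples:
  - {oxidized: nad_plus, reduced: nadh}
  - {oxidized: nadp_plus, reduced: nadph}
  - {oxidized: fd_ox, reduced: fd_red}

reactions:
  catechin_to_taxifolin:
    enzyme: "unknown oxidase"
    stoichiometry:
      catechin: -1
      h2o: -1
      nad_plus: -2
      taxifolin: 1
      nadh: 2
      h_plus: 2
  taxifolin_to_eriodictyol:
    enzyme: CDH
    stoichiometry:
      taxifolin: -1
      nadh: -1
      h_plus: -1
      eriodictyol: 1
      h2o: 1
      nad_plus: 1
  eriodictyol_to_naringenin:
    enzyme: CDH
    stoichiometry:
      eriodictyol: -1
      nadh: -1
      h_plus: -1
      naringenin: 1
      h2o: 1
      nad_plus: 1
  taxifolin_to_dihydrokaempferol:
    enzyme: CDH
    stoichiometry:
      taxifolin: -1
      nadh: -1
      h_plus: -1
      dihydrokaempferol: 1
      h2o: 1
      nad_plus: 1
  naringenin_to_phloretin:
    enzyme: FCR
    stoichiometry:
      naringenin: -1
      nadh: -1
      h_plus: -1
      phloretin: 1
      nad_plus: 1
  eriodictyol_to_dihydrochalcone:
    enzyme: FCR
    stoichiometry:
      eriodictyol: -1
      nadh: -1
      h_plus: -1
      eriodictyol_dihydrochalcone: 1
      nad_plus: 1
  phloretin_hydrolysis:
    enzyme: PHY
    stoichiometry:
      phloretin: -1
      h2o: -1
      phloroglucinol: 1
      hydroxyphenylpropionate_4: 1
  dihydrochalcone_hydrolysis:
    enzyme: PHY
    stoichiometry:
      eriodictyol_dihydrochalcone: -1
      h2o: -1
      phloroglucinol: 1
      dihydroxyphenylpropionate_34: 1
  dihydrokaempferol_to_maesopsin:
    enzyme: CHI
    stoichiometry:
      dihydrokaempferol: -1
      maesopsin: 1
  maesopsin_cleavage:
    enzyme: "auronol hydrolase"
    stoichiometry:
      maesopsin: -1
      h2o: -2
      phloroglucinol: 1
      hydroxyphenylacetate_4: 1
      formate: 1
  phloroglucinol_fermentation:
    enzyme: "PGR + beta-oxidation (lumped)"
    stoichiometry:
      phloroglucinol: -1
      h2o: -1
      nadph: -1
      nadh: -2
      fd_ox: -1
      h_plus: -1
      acetate: 1
      butyrate: 1
      nadp_plus: 1
      nad_plus: 2
      fd_red: 1
  hydrogenotrophic_methanogenesis:
    enzyme: Mcr-reference
    stoichiometry:
      co2: -1
      h2: -4
      ch4: 1
      h2o: 2

recycling:
  - name: PntAB
    enzyme: "NAD(P) transhydrogenase"
    targets: [nadp_plus]
    stoichiometry:
      nadp_plus: -1
      nadh: -1
      nadph: 1
      nad_plus: 1
  - name: Rnf
    enzyme: "ferredoxin:NAD+ oxidoreductase"
    targets: [nad_plus, fd_red]
    stoichiometry:
      fd_red: -1
      nad_plus: -1
      h_plus: -1
      fd_ox: 1
      nadh: 1
  - name: FeFe-A3
    enzyme: "electron-bifurcating [FeFe] hydrogenase"
    targets: [nad_plus]
    stoichiometry:
      h2: -2
      nad_plus: -1
      fd_ox: -1
      nadh: 1
      fd_red: 1
      h_plus: 3
  - name: NiFe-4e
    enzyme: "energy-converting [NiFe] hydrogenase"
    targets: [fd_red]
    stoichiometry:
      fd_red: -1
      h_plus: -2
      fd_ox: 1
      h2: 1

routes:
  naringenin:
    substrate: catechin
    products: [acetate, butyrate, hydroxyphenylpropionate_4]
    reactions:
      - catechin_to_taxifolin
      - taxifolin_to_eriodictyol
      - eriodictyol_to_naringenin
      - naringenin_to_phloretin
      - phloretin_hydrolysis
      - phloroglucinol_fermentation
  eriodictyol:
    substrate: catechin
    products: [acetate, butyrate, dihydroxyphenylpropionate_34]
    reactions:
      - catechin_to_taxifolin
      - taxifolin_to_eriodictyol
      - eriodictyol_to_dihydrochalcone
      - dihydrochalcone_hydrolysis
      - phloroglucinol_fermentation
  dihydrokaempferol:
    substrate: catechin
    products: [acetate, butyrate, hydroxyphenylacetate_4, formate]
    reactions:
      - catechin_to_taxifolin
      - taxifolin_to_dihydrokaempferol
      - dihydrokaempferol_to_maesopsin
      - maesopsin_cleavage
      - phloroglucinol_fermentation
  phloroglucinol:
    substrate: phloroglucinol
    products: [acetate, butyrate]
    reactions:
      - phloroglucinol_fermentation
  methanogenesis_reference:
    substrate: co2
    products: [ch4]
    reactions:
      - hydrogenotrophic_methanogenesis
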