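# Curated methanogen calling rules expressed in the generic boolean grammar.
#
# Gene sets are lists of annotation identifiers (KO unless noted) matched
# against the catalog's ko_id / cazy_best_hit / camper_id columns.  The id
# lists are curated defaults; they are configuration, not a claim of
# completeness, and curators are expected to amend them.
#
# Grammar nodes:
#   {genes: {set: NAME, min: K}}    at least K distinct genes from set NAME
#   {taxonomy: {column: COL, equals: VALUE}}
#   {all: [NODE, ...]} / {any: [NODE, ...]} / {not: NODE}

gene_sets:
  mcr: [K00399, K00401, K00402]                       # mcrABG
  hdr: [K03388, K03389, K03390, K08264, K08265]       # hdrABC, hdrDE
  wood_ljungdahl: [K00200, K00201, K00202, K00203,    # fwd/fmdABCD
                   K00672, K01499, K00319, K00320]    # ftr, mch, mtd, mer
  mtr: [K00577, K00578, K00579, K00580, K00581,
        K00582, K00583, K00584]                       # mtrA-H
  acs_codh: [K00192, K00193, K00194, K00195, K00196,
             K00197, K00198]                          # cdh subunits
  acs: [K01895]                                       # acetyl-CoA synthetase
  ack: [K00925]
  pta: [K00625]
  mtxb: [K04480, K16176, K16178, K14083, K16954]      # substrate:corrinoid MTs
  methanogen_hydrogenases: [K00440, K00441, K00442, K00443,  # frhABDG
                            K14126, K14127, K14128,          # mvhADG
                            K14086, K14087, K14088, K14089]  # echABCD
  acetate_any: [K01895, K00925, K00625]
  methanogenesis_any: [K00399, K00401, K00402, K03388, K03389, K03390,
                       K08264, K08265, K00200, K00201, K00202, K00203,
                       K00672, K01499, K00319, K00320, K00577, K00578,
                       K00579, K00580, K00581, K00582, K00583, K00584,
                       K00192, K00193, K00194, K00195, K00196, K00197,
                       K00198, K01895, K00925, K00625, K04480, K16176,
                       K16178, K14083, K16954]

confirmation:
  # a MAG is treated as a methanogen only if it encodes Mcr and Hdr
  all:
    - genes: {set: mcr, min: 1}
    - genes: {set: hdr, min: 1}

potential:
  hydrogenotrophic:
    all:
      - genes: {set: wood_ljungdahl, min: 1}
      - genes: {set: mtr, min: 1}
      - genes: {set: methanogen_hydrogenases, min: 1}
  acetoclastic:
    all:
      - taxonomy: {column: tax_class, equals: Methanosarcinia}
      - genes: {set: acs_codh, min: 1}
      - any:
          - genes: {set: acs, min: 1}
          - all:
              - genes: {set: ack, min: 1}
              - genes: {set: pta, min: 1}
  methylotrophic:
    genes: {set: mtxb, min: 1}

active:
  hydrogenotrophic:
    all:
      - genes: {set: wood_ljungdahl, min: 1}
      - genes: {set: methanogen_hydrogenases, min: 1}
  acetoclastic:
    any:
      - genes: {set: acs, min: 1}
      - all:
          - genes: {set: ack, min: 1}
          - genes: {set: pta, min: 1}
  methylotrophic:
    genes: {set: mtxb, min: 1}

# Active Methanotrichales are obligate acetoclasts regardless of other rules.
obligate_acetoclast_taxonomy: {column: tax_order, equals: Methanotrichales}

pathway_groups:
  wood_ljungdahl: wood_ljungdahl
  methyltransferase: mtxb
  acetate: acetate_any
  complex: mcr
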