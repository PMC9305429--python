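# Chemotaxonomic classification key for the 11-sample Lavandula panel.
# Each row: taxon id, binomial/cultivar, assigned chemical cluster (1-6) and
# the seven presence/absence criteria:
#   c1: compounds 8 + 14 major presence      c2: compound 53 major presence
#   c3: compounds 15 + 16 both present       c4: neither 15 nor 16 present
#   c5: depside family present (>=2 members) c6: compound 93 present
#   c7: diterpene family present (>=1 member)
# Recorded exactly as the key is printed; the loader accepts overrides for the
# typographically uncertain criterion-6 marks on the angustifolia/intermedia rows.
max_hamming: 2
rows:
  - taxon: ang_white
    species: Lavandula angustifolia cv. White
    cluster: 1
    criteria: [true, false, false, false, false, true, false]
  - taxon: ang_blue
    species: Lavandula angustifolia cv. Blue
    cluster: 1
    criteria: [true, true, true, false, false, true, false]
  - taxon: int_abrial
    species: Lavandula x intermedia cv. Abrial
    cluster: 1
    criteria: [true, false, false, false, false, true, false]
  - taxon: int_grosso
    species: Lavandula x intermedia cv. Grosso
    cluster: 1
    criteria: [true, true, true, false, false, true, false]
  - taxon: allardi
    species: Lavandula allardi
    cluster: 2
    criteria: [false, true, true, false, false, false, false]
  - taxon: dentata
    species: Lavandula dentata
    cluster: 2
    criteria: [true, true, true, false, false, false, false]
  - taxon: latifolia
    species: Lavandula latifolia
    cluster: 2
    criteria: [false, true, true, false, false, false, false]
  - taxon: pinnata
    species: Lavandula pinnata
    cluster: 3
    criteria: [false, true, false, true, false, false, false]
  - taxon: canariensis
    species: Lavandula canariensis
    cluster: 4
    criteria: [false, true, false, true, true, false, false]
  - taxon: stoechas
    species: Lavandula stoechas cv. Pedunculata
    cluster: 5
    criteria: [false, true, false, true, true, true, false]
  - taxon: perovskia
    species: Perovskia atriplicifolia
    cluster: 6
    criteria: [false, true, false, true, true, false, true]
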