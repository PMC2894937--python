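# Example phenotype-network definitions: each network name maps to the GO
# category ids whose DE members seed it. These ids match the synthetic
# study generator (`ctdnet synth study`); replace them with real GO ids
# when working from an actual annotation table.
chromosome_segregation:
  - "GO:CHRSEG"
cell_wall_membrane:
  - "GO:CELLWALL"
cell_cycle_repair:
  - "GO:CYCREP"
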