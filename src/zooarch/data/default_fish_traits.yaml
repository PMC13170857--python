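# Default taxon -> habitat-preference map for the salinity/sediment
# ordination. The category vocabulary is an ecological convention, not a
# measurement: treat this file as a starting point and override it with a
# project-specific map where taxonomic resolution allows. Salinity
# categories: marine, brackish, freshwater. Sediment categories: rock,
# sand, mud, vegetation. Entries cover common northern European fish
# taxa at species and family level.
European eel:
  salinity: [freshwater, brackish]
  sediment: [mud, vegetation]
Anguillidae:
  salinity: [freshwater, brackish]
  sediment: [mud, vegetation]
European flounder:
  salinity: [marine, brackish]
  sediment: [sand, mud]
Pleuronectidae:
  salinity: [marine, brackish]
  sediment: [sand, mud]
Atlantic cod:
  salinity: [marine]
  sediment: [rock, sand]
Gadidae:
  salinity: [marine]
  sediment: [rock, sand]
Shorthorn sculpin:
  salinity: [marine, brackish]
  sediment: [rock]
Cottidae:
  salinity: [marine, brackish]
  sediment: [rock]
Atlantic herring:
  salinity: [marine, brackish]
  sediment: [sand]
Clupeidae:
  salinity: [marine, brackish]
  sediment: [sand]
European perch:
  salinity: [freshwater, brackish]
  sediment: [vegetation]
Northern pike:
  salinity: [freshwater]
  sediment: [vegetation]
Esocidae:
  salinity: [freshwater]
  sediment: [vegetation]
Eelpout:
  salinity: [marine, brackish]
  sediment: [rock, mud]
Zoarcidae:
  salinity: [marine, brackish]
  sediment: [rock, mud]
Roach:
  salinity: [freshwater, brackish]
  sediment: [vegetation, mud]
Cyprinidae:
  salinity: [freshwater, brackish]
  sediment: [vegetation, mud]
Zander:
  salinity: [freshwater, brackish]
  sediment: [sand]
Percidae:
  salinity: [freshwater, brackish]
  sediment: [vegetation]
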