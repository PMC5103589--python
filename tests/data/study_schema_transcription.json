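{
  "_comment": "Hand-transcribed default Study-file column schemas of the Phenotyping Configuration (Basic / Field / Greenhouse). 'Protocol REF[X]' is the documentation shorthand for a Protocol REF column whose cells carry the protocol name X. Kept independent of the implementation as a frozen oracle.",
  "basic": [
    "Source Name",
    "Characteristics[Organism]",
    "Characteristics[Infraspecific name]",
    "Characteristics[Seed origin]",
    "Characteristics[Study start]",
    "Characteristics[Study duration]",
    "Characteristics[Growth facility]",
    "Characteristics[Geographic location]",
    "Sample Name"
  ],
  "field": [
    "Source Name",
    "Characteristics[Organism]",
    "Characteristics[Infraspecific name]",
    "Characteristics[Seed origin]",
    "Characteristics[Study start]",
    "Characteristics[Study duration]",
    "Characteristics[Growth facility]",
    "Characteristics[Geographic location]",
    "Protocol REF[Rooting]",
    "Parameter Value[Rooting medium]",
    "Parameter Value[Plot size]",
    "Unit",
    "Parameter Value[Sowing density]",
    "Parameter Value[pH]",
    "Protocol REF[Aerial conditions]",
    "Parameter Value[Air humidity]",
    "Parameter Value[Daily photon flux]",
    "Parameter Value[Length of light period]",
    "Parameter Value[Day temperature]",
    "Parameter Value[Night temperature]",
    "Protocol REF[Nutrition]",
    "Parameter Value[N before fertilisation]",
    "Parameter Value[Type of fertiliser]",
    "Parameter Value[Amount of fertiliser]",
    "Protocol REF[Watering]",
    "Parameter Value[Irrigation type]",
    "Parameter Value[Volume]",
    "Parameter Value[Frequency]",
    "Protocol REF[Sampling]",
    "Parameter Value[Experimental unit]",
    "Sample Name"
  ],
  "greenhouse": [
    "Source Name",
    "Characteristics[Organism]",
    "Characteristics[Infraspecific name]",
    "Characteristics[Seed origin]",
    "Characteristics[Study start]",
    "Characteristics[Study duration]",
    "Characteristics[Growth facility]",
    "Characteristics[Geographic location]",
    "Protocol REF[Rooting]",
    "Parameter Value[Rooting medium]",
    "Parameter Value[Container type]",
    "Parameter Value[Container volume]",
    "Parameter Value[Container dimension]",
    "Unit",
    "Parameter Value[Number of plants per container]",
    "Parameter Value[pH]",
    "Protocol REF[Aerial conditions]",
    "Parameter Value[Air humidity]",
    "Parameter Value[Daily photon flux]",
    "Parameter Value[Length of light period]",
    "Parameter Value[Day temperature]",
    "Parameter Value[Night temperature]",
    "Protocol REF[Nutrition]",
    "Parameter Value[N before fertilisation]",
    "Parameter Value[Type of fertiliser]",
    "Parameter Value[Amount of fertiliser]",
    "Protocol REF[Watering]",
    "Parameter Value[Irrigation type]",
    "Parameter Value[Volume]",
    "Parameter Value[Frequency]",
    "Protocol REF[Sampling]",
    "Parameter Value[Experimental unit]",
    "Sample Name"
  ]
}
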