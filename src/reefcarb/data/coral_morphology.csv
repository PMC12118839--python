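taxon,level,value,source
Porites lobata,species,1.0,editable default (massive)
Porites compressa,species,1.2,editable default (columnar/branching)
Porites evermanni,species,1.0,editable default (massive)
Porites brighami,species,1.0,editable default (encrusting)
Pocillopora meandrina,species,1.3,editable default (branching)
Pocillopora grandis,species,1.3,editable default (branching)
Pocillopora damicornis,species,1.3,editable default (branching)
Montipora capitata,species,1.1,editable default (plating)
Montipora patula,species,1.0,editable default (encrusting)
Montipora flabellata,species,1.0,editable default (encrusting)
Pavona varians,species,1.0,editable default (encrusting)
Pavona duerdeni,species,1.0,editable default (massive)
Leptastrea purpurea,species,1.0,editable default (encrusting)
Psammocora stellata,species,1.0,editable default (massive)
Fungia scutaria,species,1.0,editable default (free-living)
Porites,genus,1.0,editable default
Pocillopora,genus,1.3,editable default
Montipora,genus,1.0,editable default
Pavona,genus,1.0,editable default
Leptastrea,genus,1.0,editable default
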