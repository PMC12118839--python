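taxon,level,value,source
Porites lobata,species,1.32,editable default (g cm-3)
Porites compressa,species,1.22,editable default
Porites evermanni,species,1.30,editable default
Porites brighami,species,1.30,editable default
Pocillopora meandrina,species,1.54,editable default
Pocillopora grandis,species,1.54,editable default
Pocillopora damicornis,species,1.45,editable default
Montipora capitata,species,1.45,editable default
Montipora patula,species,1.45,editable default
Montipora flabellata,species,1.45,editable default
Pavona varians,species,1.46,editable default
Pavona duerdeni,species,1.46,editable default
Leptastrea purpurea,species,1.60,editable default
Psammocora stellata,species,1.40,editable default
Fungia scutaria,species,1.40,editable default
Porites,genus,1.28,editable default
Pocillopora,genus,1.51,editable default
Montipora,genus,1.45,editable default
Pavona,genus,1.46,editable default
Leptastrea,genus,1.60,editable default
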