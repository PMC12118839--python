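taxon,level,kind,value,source
Porites lobata,species,porites_depth_model,,depth-dependent model
Porites compressa,species,porites_depth_model,,depth-dependent model
Porites evermanni,species,porites_depth_model,,depth-dependent model
Porites brighami,species,porites_depth_model,,depth-dependent model
Porites,genus,porites_depth_model,,depth-dependent model
Pocillopora meandrina,species,fixed,2.39,editable default (cm y-1)
Pocillopora grandis,species,fixed,2.39,editable default
Pocillopora damicornis,species,fixed,2.87,editable default
Montipora capitata,species,fixed,1.10,editable default
Montipora patula,species,fixed,0.80,editable default
Montipora flabellata,species,fixed,0.80,editable default
Pavona varians,species,fixed,0.62,editable default
Pavona duerdeni,species,fixed,0.62,editable default
Leptastrea purpurea,species,fixed,0.40,editable default
Psammocora stellata,species,fixed,0.50,editable default
Fungia scutaria,species,fixed,0.60,editable default
Pocillopora,genus,fixed,2.50,editable default
Montipora,genus,fixed,0.90,editable default
Pavona,genus,fixed,0.62,editable default
Leptastrea,genus,fixed,0.40,editable default
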