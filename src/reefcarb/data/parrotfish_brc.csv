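species,level,brc,source
Chlorurus spilurus,species,2.00,editable default (bite-rate constant)
Chlorurus sordidus,species,2.00,editable default
Scarus psittacus,species,1.50,editable default
Scarus rubroviolaceus,species,1.00,editable default
Scarus dubius,species,1.50,editable default
Calotomus carolinus,species,0.50,editable default
Chlorurus,genus,2.00,editable default
Scarus,genus,1.40,editable default
Calotomus,genus,0.50,editable default
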