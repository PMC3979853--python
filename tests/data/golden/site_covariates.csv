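transect,year,veg1,veg2,veg3,veg4,water1,water2,water3,water4,litter1,litter2,litter3,litter4
T001,1,0.2,0.2,0.2,0.4,0.2,0.4,0.2,0.2,0.4,0.2,0.0,0.4
T001,2,0.2,0.2,0.4,0.2,0.4,0.0,0.2,0.4,0.0,0.4,0.6,0.0
T002,1,0.2,0.2,0.0,0.6,0.4,0.2,0.2,0.2,0.0,0.2,0.2,0.6
T002,2,0.2,0.2,0.2,0.4,0.4,0.2,0.0,0.4,0.8,0.0,0.0,0.2
T003,1,0.4,0.2,0.2,0.2,0.0,0.4,0.4,0.2,0.4,0.2,0.0,0.4
T003,2,0.0,0.0,0.6,0.4,0.6,0.0,0.0,0.4,0.6,0.4,0.0,0.0
T004,1,0.0,0.2,0.2,0.6,0.2,0.2,0.4,0.2,0.4,0.2,0.4,0.0
T004,2,0.4,0.2,0.2,0.2,0.4,0.0,0.4,0.2,0.2,0.6,0.0,0.2
T005,1,0.2,0.4,0.4,0.0,0.2,0.2,0.4,0.2,0.2,0.0,0.4,0.4
T005,2,0.2,0.6,0.0,0.2,0.0,0.4,0.4,0.2,0.2,0.2,0.4,0.2
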