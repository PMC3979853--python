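transect,year,visit,count
T001,1,1,18
T001,1,2,16
T001,1,3,15
T001,2,1,12
T001,2,2,14
T001,2,3,17
T002,1,1,5
T002,1,2,7
T002,1,3,4
T002,2,1,11
T002,2,2,9
T002,2,3,11
T003,1,1,17
T003,1,2,21
T003,1,3,23
T003,2,1,16
T003,2,2,16
T003,2,3,18
T004,1,1,12
T004,1,2,16
T004,1,3,11
T004,2,1,7
T004,2,2,8
T004,2,3,9
T005,1,1,20
T005,1,2,19
T005,1,3,20
T005,2,1,22
T005,2,2,15
T005,2,3,17
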