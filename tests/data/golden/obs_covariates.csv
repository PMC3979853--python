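transect,year,visit,rain_mm,temp_c,wind,day_of_season
T001,1,1,0.0,22.24853737167298,1.1495164992511768,30
T001,1,2,1.6462428188125353,15.110243917768026,4.906165622967705,32
T001,1,3,0.0,19.336676982543274,0.8617936138398361,35
T001,2,1,0.0,10.153989255758946,5.2217142699963155,5
T001,2,2,0.0,18.487041326480618,5.295913363053944,7
T001,2,3,0.0,21.492780371566916,2.1123711107623624,10
T002,1,1,0.0,16.389805967824437,1.6455251124613435,4
T002,1,2,0.0,21.29395215600251,2.753484121907937,6
T002,1,3,4.661127214645068,22.812938288879,1.2988732137552579,9
T002,2,1,0.0,19.074944988237746,0.3944588017590856,8
T002,2,2,0.0,10.486801547180505,2.007581372168558,10
T002,2,3,2.3902676446791338,13.695570624048418,7.29923746349623,13
T003,1,1,0.6323756436985488,15.580297800258442,0.9809602645014652,17
T003,1,2,1.3803168947767397,19.364343957407574,7.776725624532295,19
T003,1,3,0.0,12.82241614653562,1.0821197190765204,22
T003,2,1,0.0,20.10151792471962,2.1582996585233003,9
T003,2,2,0.0,15.225336203842678,2.4396501327825226,11
T003,2,3,1.860549333985912,13.511456686488886,0.10649941181328709,14
T004,1,1,0.06486501809250815,14.7533345415067,0.8175129077970518,27
T004,1,2,0.0,15.060594920539573,1.5422765592932288,29
T004,1,3,0.0,17.63919236999351,4.440362657562007,32
T004,2,1,0.0,18.339178819816183,3.9474979680644977,15
T004,2,2,0.0,18.680294574853363,1.734225730909229,17
T004,2,3,0.0,17.16912656806731,3.0397621957091854,20
T005,1,1,0.27579927598910337,22.32221136105522,2.2674839212460873,1
T005,1,2,0.8781974238369409,16.422461619426706,1.2277175606536774,3
T005,1,3,0.0,18.164760812747037,7.509824249918731,6
T005,2,1,2.1827764982580065,17.781578375846134,1.3522834756090008,19
T005,2,2,0.0,19.906585458445743,1.800624171124542,21
T005,2,3,0.0,11.699585692357406,10.17366145807939,24
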