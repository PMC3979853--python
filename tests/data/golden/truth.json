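{
 "params": {
  "beta0": 2.5,
  "trend": 0.0,
  "beta_water": [
   0.51,
   0.36,
   0.26
  ],
  "sigma_b": 0.6,
  "alpha_det": 0.25,
  "sigma_year": 0.3,
  "alpha_rain": 0.01,
  "alpha_veg": [
   0.65,
   0.7,
   0.15
  ]
 },
 "alpha_year": [
  0.2675954914553674,
  0.49188048684622043
 ],
 "b": [
  0.3225401122153434,
  -0.3308609990954591,
  0.4819821550237629,
  -0.22632917940956848,
  0.507945709905902
 ],
 "site_years": [
  [
   "T001",
   1
  ],
  [
   "T001",
   2
  ],
  [
   "T002",
   1
  ],
  [
   "T002",
   2
  ],
  [
   "T003",
   1
  ],
  [
   "T003",
   2
  ],
  [
   "T004",
   1
  ],
  [
   "T004",
   2
  ],
  [
   "T005",
   1
  ],
  [
   "T005",
   2
  ]
 ],
 "lam": [
  23.348672078906255,
  20.056235686647963,
  10.96972275449638,
  10.752507690500277,
  29.429046270921706,
  21.88895463493572,
  13.08767333715142,
  11.818555786036562,
  27.274322993446383,
  30.20313448551165
 ],
 "N": [
  23,
  19,
  7,
  15,
  35,
  24,
  16,
  13,
  31,
  24
 ],
 "p": [
  [
   0.6439434337865831,
   0.6475325616281429,
   0.6439434337865831
  ],
  [
   0.7164268979141227,
   0.7164268979141227,
   0.7164268979141227
  ],
  [
   0.6183430599988688,
   0.6183430599988688,
   0.6287701305959392
  ],
  [
   0.6935579795977622,
   0.6935579795977622,
   0.698378179959374
  ],
  [
   0.6384281003229157,
   0.6400719454466933,
   0.637035713592805
  ],
  [
   0.7244824621507554,
   0.7244824621507554,
   0.7280077826467678
  ],
  [
   0.6509322353514024,
   0.6507917556771792,
   0.6507917556771792
  ],
  [
   0.6871451637453179,
   0.6871451637453179,
   0.6871451637453179
  ],
  [
   0.6910749913786414,
   0.692299329682692,
   0.6905135476879737
  ],
  [
   0.7165900086327319,
   0.7123461824480877,
   0.7123461824480877
  ]
 ],
 "rain_z": [
  [
   -0.5074217031568093,
   1.0615344510241584,
   -0.5074217031568093
  ],
  [
   -0.5074217031568093,
   -0.5074217031568093,
   -0.5074217031568093
  ],
  [
   -0.5074217031568093,
   -0.5074217031568093,
   3.934878147914279
  ],
  [
   -0.5074217031568093,
   -0.5074217031568093,
   1.7706293160507214
  ],
  [
   0.09526560797184856,
   0.808093032598914,
   -0.5074217031568093
  ],
  [
   -0.5074217031568093,
   -0.5074217031568093,
   1.2657798527473874
  ],
  [
   -0.4456019228884833,
   -0.5074217031568093,
   -0.5074217031568093
  ],
  [
   -0.5074217031568093,
   -0.5074217031568093,
   -0.5074217031568093
  ],
  [
   -0.24457046004925512,
   0.32954671788615125,
   -0.5074217031568093
  ],
  [
   1.5728793198804643,
   -0.5074217031568093,
   -0.5074217031568093
  ]
 ]
}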