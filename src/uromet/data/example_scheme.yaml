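# Minimal example bucket scheme for `uromet bucket`.
# Buckets are [left, right) intervals in descending ppm; the exclusions are
# the standard urine-NMR regions (urea, water, TSP reference).
buckets:
  - {id: B1.330, left: 1.345, right: 1.315}   # lactate CH3 doublet
  - {id: B1.480, left: 1.495, right: 1.465}   # alanine CH3 doublet
  - {id: B1.920, left: 1.935, right: 1.905}   # acetate singlet
  - {id: B2.410, left: 2.425, right: 2.395}   # succinate singlet
  - {id: B2.540, left: 2.555, right: 2.525}   # citrate AB half
  - {id: B2.660, left: 2.675, right: 2.645}   # citrate AB half
  - {id: B3.050, left: 3.065, right: 3.035}   # creatinine N-CH3
  - {id: B3.260, left: 3.275, right: 3.245}   # taurine N-CH2
  - {id: B4.060, left: 4.075, right: 4.045}   # creatinine CH2
  - {id: B7.830, left: 7.845, right: 7.815}   # hippurate aromatic
exclusions:
  - [6.20, 5.40]
  - [5.00, 4.50]
  - [0.20, -0.20]
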