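# Default synthetic smelter gradient: three sites at 0, 5 and 60 km.
# Source strengths are polluted-topsoil magnitudes (mg/kg), decay rates put
# the 60 km site at rural background levels, and partition ratios follow
# field-observed chain averages for grapevine.
seed: 0
sites:
  - [Near, 0.0]
  - [Mid, 5.0]
  - [Far, 60.0]
varieties: [Feteasca alba, Feteasca regala, Italian Riesling]
cv_noise: 0.1
n_replicates: 3
elements:
  Cu:
    source_strength: 2510.0
    decay_per_km: 0.0233
    partition: {root/soil: 0.45, cane/root: 0.18, leaf/cane: 0.98, grape/cane: 0.11, must/grape: 2.19, wine/must: 0.06}
    loq: 0.001
  Zn:
    source_strength: 1638.0
    decay_per_km: 0.0510
    partition: {root/soil: 0.18, cane/root: 1.02, leaf/cane: 0.86, grape/cane: 0.05, must/grape: 2.28, wine/must: 0.33}
    loq: 0.001
  Pb:
    source_strength: 3074.0
    decay_per_km: 0.0916
    partition: {root/soil: 0.05, cane/root: 1.16, leaf/cane: 1.22, grape/cane: 0.09, must/grape: 0.13, wine/must: 0.30}
    loq: 0.001
  Cd:
    source_strength: 14.1
    decay_per_km: 0.0659
    partition: {root/soil: 0.58, cane/root: 1.73, leaf/cane: 0.68, grape/cane: 0.15, must/grape: 0.11, wine/must: 0.33}
    loq: 0.001
  Ni:
    source_strength: 28.6
    decay_per_km: 0.0217
    partition: {root/soil: 0.82, cane/root: 1.12, leaf/cane: 2.57, grape/cane: 0.20, must/grape: 0.34, wine/must: 0.14}
    loq: 0.001
  Co:
    source_strength: 29.6
    decay_per_km: 0.0293
    partition: {root/soil: 2.17, cane/root: 2.28, leaf/cane: 1.35, grape/cane: 0.11, must/grape: 0.0, wine/must: 0.0}
    loq: 0.001
  As:
    source_strength: 4.13
    decay_per_km: 0.0121
    partition: {root/soil: 1.30, cane/root: 0.62, leaf/cane: 2.23, grape/cane: 0.53, must/grape: 0.07, wine/must: 0.66}
    loq: 0.001
  Cr:
    source_strength: 2.25
    decay_per_km: 0.0142
    partition: {root/soil: 2.90, cane/root: 0.23, leaf/cane: 0.51, grape/cane: 0.24, must/grape: 4.54, wine/must: 0.85}
    loq: 0.001
  Hg:
    source_strength: 0.058
    decay_per_km: 0.0032
    partition: {root/soil: 0.60, cane/root: 1.41, leaf/cane: 1.93, grape/cane: 0.53, must/grape: 0.02, wine/must: 0.08}
    loq: 0.0001
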