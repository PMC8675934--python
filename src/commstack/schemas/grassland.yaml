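# Default column layout: 23 annual-plant species codes (synthetic community
# labels styled after Mediterranean salt-grassland flora) and the 13 soil
# variables measured once per subplot plus year-level precipitation.
species:
  - ACHI
  - ANAR
  - BEMA
  - CETE
  - CHFU
  - CHMI
  - COSQ
  - FRPU
  - HOMA
  - LEMA
  - LYTR
  - MEEL
  - MESU
  - PAIN
  - PLCO
  - POMA
  - POMO
  - PUPA
  - SASO
  - SCLA
  - SOAS
  - SPRU
  - SUSP
soil_variables:
  - pH
  - salinity
  - carbonates
  - organic_matter
  - cn_ratio
  - Cl
  - C
  - N
  - P
  - Ca
  - Mg
  - K
  - Na
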