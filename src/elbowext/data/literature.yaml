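# Cadaver-scale literature defaults used for PCSA scaling.
#
# Per-head physiological cross-sectional areas (cm^2) and the cadaver upper-
# arm circumference (cm) they were measured at. Subject PCSA is obtained by
# scaling these linearly with the ratio of the subject's upper-arm
# circumference to the cadaver value. Values are representative cadaver-
# study magnitudes for the three triceps heads and are config-overridable.
pcsa:
  MHT: 6.1
  LatHT: 6.0
  LngHT: 6.7
cadaver_arm_circumference: 29.4
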