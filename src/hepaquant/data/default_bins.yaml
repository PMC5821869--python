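# Default surrogate-to-ordinal bin thresholds for the four
# necroinflammatory categories (Ishak-style ordinal ranges 0-4, 0-6,
# 0-4, 0-4; composite 0-18).  An ordinal is the number of thresholds
# strictly below the measure.
#
# Units: piecemeal / portal are CD45+ cells per mm^2 of the periportal
# band / portal regions; confluent is the necrotic fraction of tissue
# area; lobular is inflammatory foci per mm^2 of lobular tissue.
#
# Calibrated once as even partitions of the synthetic severity ladder's
# planted measure ranges (severity 0..10).
thresholds:
  piecemeal: [110.0, 280.0, 450.0, 620.0]
  confluent: [0.004, 0.011, 0.019, 0.030, 0.041, 0.052]
  lobular: [8.0, 20.0, 33.0, 44.0]
  portal: [110.0, 280.0, 450.0, 620.0]
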