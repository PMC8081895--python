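# Biomarkers proposed by the prior experimental expression studies;
# intersecting with the network-prioritized set yields the 13 jointly
# supported candidates.
ALOX5
CCL5
CHI3L1
IFNG
IL10
IL1R2
IL4R
IL8
SELL
SERPINB2
TGFB1
TLR4
TNF
MSR1
PI3
PHLDA1
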