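treatment,week,mean_null,mean_alt,sem,sd
HFol-HFol,1,160,166.45,7.97,27.57
HFol-RV,1,160,165.27,6.79,23.48
RV-RV,1,160,149.92,6.00,20.76
HFol-HFol,7,480,478.77,8.26,28.59
HFol-RV,7,480,492.34,12.98,44.92
RV-RV,7,480,468.14,11.21,38.80
HFol-HFol,14,630,615.83,17.70,61.26
HFol-RV,14,630,654.19,21.54,74.53
RV-RV,14,630,619.96,15.34,53.09
HFol-HFol,21,724,697.41,19.48,67.38
HFol-RV,21,724,752.89,26.85,92.91
RV-RV,21,724,721.02,16.23,56.15
HFol-HFol,28,800,764.83,23.90,82.70
HFol-RV,28,800,835.06,33.05,114.35
RV-RV,28,800,790.21,15.64,54.11
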