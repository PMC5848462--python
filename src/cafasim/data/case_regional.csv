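region,side,cbf_pld1,cbf_pld2,cbf_pld3,att
fronto-temporal,left,51.76,50.61,52.38,1.23
fronto-temporal,right,52.93,49.73,48.02,1.13
fronto-parietal,left,32.54,49.55,54.76,1.40
fronto-parietal,right,36.98,49.78,53.05,1.31
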