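ipa,word,f1_hz,f2_hz,emg1_cart,emg2_cart,emg1_polar,emg2_polar
ɑ,hot,768,1333,0.71,0.30,0.28,0.62
e,get,580,1799,0.44,0.52,0.23,0.27
i,bee,342,2322,0.10,0.77,0.72,0.21
ɔ,bought,652,997,0.54,0.14,0.51,0.72
u,boot,378,997,0.15,0.14,0.53,0.80
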