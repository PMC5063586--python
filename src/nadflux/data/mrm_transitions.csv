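metabolite,ms1_mz,ms2_mz,fragmentation_v,collision_energy_v,cell_ac_v
NAD,664,428,160,22,7
D4-NAD,668,428,160,22,7
D3-NAD,667,428,160,22,7
NaAD,669,428,150,20,7
NMN,335,123,90,11,1
NaMN,336,124,80,10,7
ATP,508,136,90,30,2
ADP,428,136,50,30,3
AMP,348,136,30,30,7
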