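complex_id,affinity_value,affinity_unit,affinity_type,dg_calculated,dg_correction,dg_experimental
6GGN,0.08,nM,IC50,-17.05,1.04,-13.76
5OC8,0.21,nM,Ki,-14.91,1.15,-13.18
4ZYF,1.3,nM,Ki,-12.89,1.34,-12.11
5LAZ,4,nM,IC50,-12.57,1.0,-11.44
5LAY,34,nM,IC50,-12.04,0.98,-10.19
5LAW,80,nM,IC50,-11.06,1.00,-9.68
WK298,109,nM,Ki,-10.885,1.15,-9.49
3TJ2,300,nM,Ki,-11.64,1.028,-8.89
4MDN,600,nM,Ki,-9.79,1.19,-8.47
5LAV,819,nM,IC50,-15.80,1.15,-8.29
4MDQ,900,nM,Ki,-12.52,1.66,-8.24
3LBK,916,nM,Ki,-10.49,1.12,-8.22
4JV7,1000,nM,IC50,-14.56,1.42,-8.63
4JV9,1800,nM,IC50,-15.73,1.62,-8.27
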