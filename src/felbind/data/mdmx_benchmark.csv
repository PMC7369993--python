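complex_id,affinity_value,affinity_unit,affinity_type,dg_calculated,dg_correction,dg_experimental
3LBJ,11.0,uM,IC50,-6.56,,-6.76
WK23,36.0,uM,IC50,-5.90,,-6.05
2N14,7.0,uM,IC50,-5.95,,-7.3
2N0U,8.6,uM,IC50,-10.48,,-8.6
2N06,24.9,uM,IC50,-7.20,,-6.7
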