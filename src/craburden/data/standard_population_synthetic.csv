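age_group,weight
40-44,0.14855328322956285
45-49,0.14112561906808468
50-54,0.13406933811468047
55-59,0.12736587120894644
60-64,0.1209975776484991
65-69,0.11494769876607414
70-74,0.10920031382777043
75-79,0.10374029813638197
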