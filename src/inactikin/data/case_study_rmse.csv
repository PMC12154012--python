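case,source_figure,organism,medium,isothermal_temps_C,processing_condition,temp_range_C,rmse_path_independent,rmse_derivative
I,2a,Bacillus sporothermodurans IC4 spores,McIlvaine pH7,"115;120;125;130",HR = 1 C/min,110-124,1.45,2.54
I,2e,Bacillus sporothermodurans IC4 spores,McIlvaine pH7,"115;120;125;130",HR = 10 C/min,110-130,0.382,0.762
I,3a,Bacillus sporothermodurans IC4 spores,McIlvaine pH7,"115;120;125;130",CR = 1 C/min,110-126,6.82,5.95
I,3b,Bacillus sporothermodurans IC4 spores,McIlvaine pH7,"115;120;125;130",CR = 10 C/min,110-130,0.437,0.584
I,2b,Bacillus sporothermodurans IC4 spores,McIlvaine pH5,"115;120;125;130",HR = 1 C/min,110-124,0.228,0.975
I,2f,Bacillus sporothermodurans IC4 spores,McIlvaine pH5,"115;120;125;130",HR = 10 C/min,110-130,0.812,2.08
I,2c,Bacillus sporothermodurans IC4 spores,McIlvaine pH3,"115;120;125;130",HR = 1 C/min,110-124,0.355,0.447
I,2g,Bacillus sporothermodurans IC4 spores,McIlvaine pH3,"115;120;125;130",HR = 10 C/min,110-130,1.15,0.851
I,2d,Bacillus sporothermodurans IC4 spores,Courgette soup,"115;120;125;130",HR = 1 C/min,110-124,0.395,1.69
I,2h,Bacillus sporothermodurans IC4 spores,Courgette soup,"115;120;125;130",HR = 10 C/min,110-130,0.836,2.46
II,3e,Geobacillus stearothermophilus T26,Distilled water,"120;122.5;125;127.5",HR = 1 C/min,90-130,1.41,1.69
II,3f,Geobacillus stearothermophilus T26,Distilled water,"120;122.5;125;127.5",HR = 20 C/min,90-130,0.874,1.12
II,4c,Geobacillus stearothermophilus T26,Distilled water,"120;122.5;125;127.5",Heating holding and cooling,83-122.5,1.43,1.62
III,6,Listeria monocytogenes,Ground beef,"57;60;63;66",HR = 1.72 C/min,30-65,0.389,7.56
IV,6a,Staphylococcus aureus,Peptone water,"55;57.5;60;62.5",Heat-exchanger profile 700 mL/min,30-65,0.914,1.80
IV,6b,Salmonella senftenberg,Peptone water,"55;57.5;60;62.5",Heat-exchanger profile 700 mL/min,30-65,0.832,2.08
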