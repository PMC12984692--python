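day,alfalfa_hay,hay,grass_hay,beet,urea,milk_performer_170a1,citrus_pulp,fat,yeast,flaked_maize_soybean,cottonseed,salt,bicarbonate
1,4.00,3.25,3.00,1.00,0.02,10.00,21.00,0.20,0.05,4.10,1.50,0.10,0.20
11,4.00,3.25,3.00,1.00,0.02,10.50,23.00,0.20,0.05,4.60,1.50,0.10,0.20
18,3.50,3.25,3.00,1.00,0.02,11.00,27.00,0.20,0.05,5.10,1.50,0.10,0.20
20,3.50,3.25,4.60,1.00,0.02,11.00,27.00,0.20,0.05,5.10,1.50,0.10,0.20
22,3.50,3.25,5.20,1.00,0.02,11.00,27.00,0.20,0.05,5.10,1.50,0.10,0.20
26,3.50,3.25,5.50,1.00,0.02,11.00,27.00,0.20,0.05,5.10,1.50,0.10,0.20
30,3.50,3.25,2.50,1.00,0.02,11.00,27.00,0.20,0.05,5.10,1.50,0.10,0.20
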