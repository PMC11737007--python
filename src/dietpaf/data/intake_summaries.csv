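factor_id,sex,prevalence,mean,sd,n
processed_meat,male,0.87,40.7,31.0,1068
processed_meat,female,0.80,29.3,22.4,1244
red_meat,male,0.83,75.0,51.4,1068
red_meat,female,0.80,60.3,37.8,1244
fiber,male,1.00,19.6,7.3,1068
fiber,female,1.00,17.7,6.3,1244
dairy,male,0.99,178.5,126.0,1068
dairy,female,0.99,194.5,117.0,1244
vegetables,male,1.00,232.9,120.2,1068
vegetables,female,1.00,213.3,102.6,1244
fruit,male,0.93,214.7,157.8,1068
fruit,female,0.95,228.2,143.8,1244
citrus,male,0.45,,,1068
citrus,female,0.51,,,1244
coffee,male,0.91,,,1068
coffee,female,0.88,,,1244
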