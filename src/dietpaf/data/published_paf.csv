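factor_id,cancer_id,sex,paf_pct,ci_low_pct,ci_high_pct
processed_meat,colorectum,male,10.5,5.0,16.3
processed_meat,colorectum,female,7.0,3.4,11.0
red_meat,colorectum,male,3.3,0.1,7.0
red_meat,colorectum,female,2.0,0.1,4.2
dairy,colorectum,male,4.8,3.6,5.9
dairy,colorectum,female,4.3,3.2,5.3
fiber,colorectum,male,7.9,0.4,14.5
fiber,colorectum,female,9.0,0.5,16.8
vegetables,mouth_pharynx_larynx,male,8.9,0.0,18.1
vegetables,mouth_pharynx_larynx,female,9.7,0.0,19.8
vegetables,nasopharynx,male,16.5,5.2,26.8
vegetables,nasopharynx,female,17.8,5.7,29.0
vegetables,esophagus_ac,male,6.3,0.7,11.4
vegetables,esophagus_ac,female,6.9,0.7,12.6
vegetables,esophagus_scc,male,5.1,0.0,10.9
vegetables,esophagus_scc,female,5.6,0.0,12.1
vegetables,colorectum,male,1.1,0.3,1.8
vegetables,colorectum,female,1.2,0.3,2.0
vegetables,lung,male,3.3,0.8,5.5
vegetables,lung,female,3.7,0.9,6.2
fruit,esophagus_scc,male,7.3,2.8,11.4
fruit,esophagus_scc,female,5.6,2.1,8.8
fruit,stomach,male,0.8,0.0,2.3
fruit,stomach,female,0.6,0.0,1.8
fruit,lung,male,3.4,2.3,4.5
fruit,lung,female,2.6,1.7,3.4
citrus,stomach_cardia,male,6.3,0.4,13.0
citrus,stomach_cardia,female,7.1,0.4,14.5
coffee,liver,male,31.9,19.7,42.8
coffee,liver,female,31.2,19.2,42.0
coffee,endometrium,female,11.6,4.1,19.0
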