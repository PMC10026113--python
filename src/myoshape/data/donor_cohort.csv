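Donor,Age,Sex,Ethnicity,CatalogueNumber,Tissue,Diabetes,BMI,Tobacco,Alcohol,NonIVDrug,FusionIndex,CD56
37M,37,M,Caucasian,01242-37M,AR,0,38,1,1,1,0.380,5.7
18M,18,M,Caucasian,01236-18M,AR,0,21,0,0,0,0.734,30.1
41M,41,M,Caucasian,01033-41M,AR,0,25,1,1,0,0.743,58.9
32F,32,F,Caucasian,01034-32F,AR,0,42,1,0,0,0.722,37.6
16F,16,F,Caucasian,01055-16F,AR,0,37,0,0,0,0.673,35.3
36F,36,F,Caucasian,01277-36F,AR,0,26,1,1,0,0.703,75.2
52F,52,F,African American,01035-52F,AR,0,47,1,0,1,0.694,62.8
51M,51,M,Caucasian,01267-51M,AR,0,26,0,0,1,0.824,76.7
31M,31,M,Caucasian,01266-31M,AR,0,28,1,1,1,0.753,63.5
42F,42,F,Caucasian,01269-42F,AR,0,35,1,0,0,0.653,45.6
49F,49,F,Caucasian,P01288-49F,AR,0,30,1,1,1,0.767,83.2
70F,70,F,Caucasian,P01402-70F,VL,0,26,0,0,0,0.485,59.3
81F,81,F,Caucasian,P01442-81F,VL,0,32,0,0,0,0.676,43.2
92F,92,F,Caucasian,P01520-92F,VL,0,26,0,0,0,0.000,54.0
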