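cause,label,age_group,phmrc,interva5
01.01,Sepsis (non-obstetric),5plus,0.22,0.17
01.01,Sepsis (non-obstetric),under5,2.68,1.13
01.02,Acute resp infect incl pneumonia,5plus,7.00,7.23
01.02,Acute resp infect incl pneumonia,under5,12.93,13.72
01.03,HIV/AIDS related death,5plus,6.06,7.70
01.03,HIV/AIDS related death,under5,0.42,0.84
01.04,Diarrhoeal diseases,5plus,3.09,2.63
01.04,Diarrhoeal diseases,under5,5.52,9.27
01.05,Malaria,5plus,1.40,0.46
01.05,Malaria,under5,2.79,1.58
01.06,Measles,5plus,0.12,0.00
01.06,Measles,under5,0.21,0.05
01.07,Meningitis and encephalitis,5plus,0.24,0.57
01.07,Meningitis and encephalitis,under5,1.95,3.03
01.08&10.05,Tetanus,under5,0.00,0.11
01.09,Pulmonary tuberculosis,5plus,3.16,6.52
01.09,Pulmonary tuberculosis,under5,0.16,0.00
01.10,Pertussis,under5,0.00,0.27
01.11,Haemorrhagic fever,5plus,0.34,0.14
01.11,Haemorrhagic fever,under5,0.89,0.31
01.99,Other and unspecified infect dis,5plus,3.31,3.30
01.99,Other and unspecified infect dis,under5,0.74,1.10
02.01,Oral neoplasms,5plus,0.29,0.07
02.02,Digestive neoplasms,5plus,2.73,5.14
02.03,Respiratory neoplasms,5plus,1.40,1.38
02.04,Breast neoplasms,5plus,2.27,1.40
02.05&02.06,Reproductive neoplasms m&f,5plus,2.78,2.87
02.99,Other and unspecified neoplasms,5plus,3.41,0.83
02.99,Other and unspecified neoplasms,under5,0.26,0.00
03.02,Severe malnutrition,5plus,0.00,0.30
03.02,Severe malnutrition,under5,0.00,2.00
03.03,Diabetes mellitus,5plus,5.14,4.12
03.03,Diabetes mellitus,under5,0.00,0.11
04.01,Acute cardiac disease,5plus,5.12,6.13
04.02,Stroke,5plus,7.37,10.27
04.03,Sickle cell with crisis,5plus,0.00,0.08
04.03,Sickle cell with crisis,under5,0.00,0.50
04.99,Other and unspecified cardiac dis,5plus,5.19,6.10
04.99,Other and unspecified cardiac dis,under5,1.63,0.09
05.01,Chronic obstructive pulmonary dis,5plus,1.98,0.61
05.02,Asthma,5plus,0.65,0.04
06.01,Acute abdomen,5plus,0.00,0.68
06.01,Acute abdomen,under5,0.00,0.20
06.02,Liver cirrhosis,5plus,3.74,3.86
07.01,Renal failure,5plus,4.81,3.13
08.01,Epilepsy,5plus,0.39,0.39
08.01,Epilepsy,under5,0.00,0.18
09.01,Ectopic pregnancy,5plus,0.00,0.08
09.02,Abortion-related death,5plus,0.00,1.78
09.03,Pregnancy-induced hypertension,5plus,1.50,1.21
09.04,Obstetric haemorrhage,5plus,1.55,1.07
09.05,Obstructed labour,5plus,0.27,0.00
09.06,Pregnancy-related sepsis,5plus,0.75,0.14
09.07,Anaemia of pregnancy,5plus,0.70,0.00
09.08,Ruptured uterus,5plus,0.00,0.02
09.99,Other and unspecified maternal CoD,5plus,1.04,0.27
10.01,Prematurity,under5,8.41,15.81
10.02,Birth asphyxia,under5,14.41,8.02
10.03,Neonatal pneumonia,under5,5.05,1.77
10.04,Neonatal sepsis,under5,5.57,2.10
10.06,Congenital malformation,under5,6.31,8.93
10.99,Other and unspecified neonatal CoD,under5,0.00,0.11
11.99,Stillbirth,under5,25.24,25.47
12.01,Road traffic accident,5plus,3.41,4.18
12.01,Road traffic accident,under5,0.58,0.78
12.03,Accidental fall,5plus,2.27,1.52
12.03,Accidental fall,under5,0.47,0.44
12.04,Accidental drowning and submersion,5plus,1.76,0.82
12.04,Accidental drowning and submersion,under5,0.53,0.46
12.05,Accidental exposure to smoke fire & flame,5plus,1.84,1.21
12.05,Accidental exposure to smoke fire & flame,under5,1.00,0.64
12.06,Contact with venomous plant/animal,5plus,1.23,0.84
12.06,Contact with venomous plant/animal,under5,0.32,0.23
12.07,Accidental poisoning & noxious substances,5plus,1.16,0.12
12.07,Accidental poisoning & noxious substances,under5,0.21,0.17
12.08,Intentional self-harm,5plus,1.69,3.61
12.09,Assault,5plus,2.61,4.06
12.09,Assault,under5,0.37,0.56
12.99,Other and unspecified external CoD,5plus,1.16,0.05
12.99,Other and unspecified external CoD,under5,0.00,0.02
98,Other and unspecified NCD,5plus,4.86,2.89
98,Other and unspecified NCD,under5,1.37,0.00
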