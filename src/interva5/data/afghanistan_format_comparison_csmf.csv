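cause,label,age_group,who2016,who2012,tariff2
01.01,Sepsis (non-obstetric),5plus,0.02,0.04,0.18
01.01,Sepsis (non-obstetric),under5,0.64,0.32,1.21
01.02,Acute resp infect incl pneumonia,5plus,2.20,3.24,3.52
01.02,Acute resp infect incl pneumonia,under5,12.24,14.27,12.68
01.03,HIV/AIDS related death,5plus,0.75,1.02,0.00
01.03,HIV/AIDS related death,under5,0.33,0.10,0.10
01.04,Diarrhoeal diseases,5plus,2.80,3.08,0.59
01.04,Diarrhoeal diseases,under5,14.25,10.91,6.92
01.05,Malaria,5plus,0.05,0.30,0.00
01.05,Malaria,under5,0.03,0.18,0.00
01.06,Measles,5plus,0.05,0.00,0.00
01.06,Measles,under5,0.17,0.05,0.07
01.07,Meningitis and encephalitis,5plus,1.26,1.46,1.49
01.07,Meningitis and encephalitis,under5,2.06,2.52,2.30
01.08,Tetanus,5plus,0.00,0.05,0.00
01.09,Pulmonary tuberculosis,5plus,10.62,12.37,6.97
01.09,Pulmonary tuberculosis,under5,0.15,0.15,0.13
01.10,Pertussis,under5,0.35,0.05,0.78
01.11,Haemorrhagic fever (non-dengue),5plus,0.23,0.04,0.00
01.11,Haemorrhagic fever (non-dengue),under5,0.00,0.00,0.05
01.12,Dengue fever,under5,0.09,0.00,0.20
01.99,Other and unspecified infect dis,5plus,0.82,0.50,0.66
01.99,Other and unspecified infect dis,under5,0.28,0.14,1.41
02.01,Oral neoplasms,5plus,0.35,0.69,0.34
02.02,Digestive neoplasms,5plus,8.24,7.37,9.74
02.03,Respiratory neoplasms,5plus,4.15,4.49,1.97
02.04,Breast neoplasms,5plus,0.96,0.96,0.37
02.05&02.06,Reproductive neoplasms m&f,5plus,0.68,0.91,0.56
02.99,Other and unspecified neoplasms,5plus,5.96,4.25,2.88
02.99,Other and unspecified neoplasms,under5,0.10,0.00,0.20
03.01,Severe anaemia,5plus,0.08,0.18,0.03
03.01,Severe anaemia,under5,0.00,0.00,0.04
03.02,Severe malnutrition,5plus,2.20,4.08,0.23
03.02,Severe malnutrition,under5,5.92,8.21,2.54
03.03,Diabetes mellitus,5plus,1.45,1.85,4.07
03.03,Diabetes mellitus,under5,0.05,0.00,0.39
04.01,Acute cardiac disease,5plus,4.73,2.24,5.24
04.02,Stroke,5plus,7.25,6.00,3.73
04.02,Stroke,under5,0.00,0.00,0.03
04.99,Other and unspecified cardiac dis,5plus,5.67,3.71,5.75
04.99,Other and unspecified cardiac dis,under5,0.00,0.00,0.12
05.01,Chronic obstructive pulmonary dis,5plus,0.97,1.58,1.24
05.02,Asthma,5plus,0.39,0.65,0.60
05.02,Asthma,under5,0.00,0.00,0.05
06.01,Acute abdomen,5plus,0.39,1.84,1.65
06.01,Acute abdomen,under5,0.05,0.13,1.34
06.02,Liver cirrhosis,5plus,1.58,1.02,4.70
06.02,Liver cirrhosis,under5,0.00,0.09,2.12
07.01,Renal failure,5plus,0.74,0.33,2.16
07.01,Renal failure,under5,0.00,0.00,0.17
08.01,Epilepsy,5plus,0.41,0.50,0.64
08.01,Epilepsy,under5,0.10,0.10,0.81
09.02,Abortion-related death,5plus,0.05,0.00,0.27
09.03,Pregnancy-induced hypertension,5plus,0.99,0.99,0.31
09.04,Obstetric haemorrhage,5plus,1.73,1.73,2.10
09.05,Obstructed labour,5plus,0.00,0.03,0.00
09.06,Pregnancy-related sepsis,5plus,0.04,0.09,0.08
09.07,Anaemia of pregnancy,5plus,0.00,0.00,0.11
09.08,Ruptured uterus,5plus,0.08,0.05,0.48
09.99,Other and unspecified maternal CoD,5plus,0.00,0.00,0.14
10.01,Prematurity,under5,6.99,3.31,6.85
10.02,Birth asphyxia,under5,9.22,9.43,5.25
10.03,Neonatal pneumonia,under5,4.81,6.55,6.82
10.04,Neonatal sepsis,under5,1.36,2.15,1.07
10.06,Congenital malformation,under5,3.48,3.31,3.43
10.99,Other and unspecified neonatal CoD,under5,1.10,2.79,1.83
11.01,Fresh stillbirth,under5,18.27,19.71,16.91
11.02,Macerated stillbirth,under5,3.58,4.05,4.05
12.01,Road traffic accident,5plus,7.13,5.07,5.21
12.01,Road traffic accident,under5,0.66,0.66,0.65
12.03,Accidental fall,5plus,1.48,0.84,0.88
12.03,Accidental fall,under5,0.58,0.49,0.60
12.04,Accidental drowning and submersion,5plus,1.01,0.79,0.79
12.04,Accidental drowning and submersion,under5,0.67,0.67,0.70
12.05,Accidental exposure to smoke fire & flame,5plus,0.44,0.38,0.35
12.05,Accidental exposure to smoke fire & flame,under5,0.35,0.30,0.35
12.06,Contact with venomous plant/animal,5plus,0.14,0.14,0.14
12.06,Contact with venomous plant/animal,under5,0.36,0.41,0.41
12.07,Accidental poisoning & noxious substances,5plus,0.13,0.12,0.06
12.07,Accidental poisoning & noxious substances,under5,0.00,0.08,0.00
12.08,Intentional self-harm,5plus,0.77,0.77,0.41
12.09,Assault,5plus,4.99,5.78,4.86
12.09,Assault,under5,0.05,0.05,0.05
12.99,Other and unspecified external CoD,5plus,0.26,0.25,0.15
12.99,Other and unspecified external CoD,under5,0.15,0.10,0.10
98,Other and unspecified NCD,5plus,1.17,1.51,1.78
98,Other and unspecified NCD,under5,0.00,0.00,0.04
99,Indeterminate,5plus,14.60,16.70,22.57
99,Indeterminate,under5,11.56,8.71,17.23
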