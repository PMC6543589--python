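broad_group,age_group,who2016,who2012,tariff2
Infections,5plus,18.80,22.10,13.41
Infections,under5,30.59,28.69,25.85
Neoplasms,5plus,20.34,18.67,15.86
Neoplasms,under5,0.10,0.00,0.20
Cardiovascular diseases,5plus,17.65,11.95,14.72
Cardiovascular diseases,under5,0.00,0.00,0.15
Other non-communicable diseases,5plus,9.37,13.55,17.10
Other non-communicable diseases,under5,6.12,8.54,7.50
Maternal and neonatal causes,5plus,2.89,2.89,3.49
Maternal and neonatal causes,under5,26.96,27.54,25.25
Stillbirths,under5,21.85,23.76,20.96
External causes,5plus,16.35,14.14,12.85
External causes,under5,2.82,2.76,2.86
Indeterminate,5plus,14.60,16.70,22.57
Indeterminate,under5,11.56,8.71,17.23
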