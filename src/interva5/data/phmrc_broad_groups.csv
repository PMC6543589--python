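broad_group,age_group,phmrc,interva5
Infections,5plus,21.63,28.72
Infections,under5,28.29,31.41
Neoplasms,5plus,12.88,11.69
Neoplasms,under5,0.26,0.00
Cardiovascular diseases,5plus,17.68,22.58
Cardiovascular diseases,under5,1.63,0.59
Other non-communicable diseases,5plus,24.87,16.03
Other non-communicable diseases,under5,26.59,27.96
Maternal and neonatal causes,5plus,5.81,4.57
Maternal and neonatal causes,under5,39.75,36.74
Stillbirths,under5,25.24,25.47
External causes,5plus,17.13,16.41
External causes,under5,3.48,3.30
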