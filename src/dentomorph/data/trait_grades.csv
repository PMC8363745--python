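specimen_id,population,tooth_class,trait,grade
A113,Egyptian,ldm2,entoconulid,0
A113,Egyptian,ldm2,metaconulid,0
A5380,SouthAmerican,ldm2,entoconulid,0
A5380,SouthAmerican,ldm2,metaconulid,0
A5380,SouthAmerican,udm2,carabelli,0
A5380,SouthAmerican,udm2,hypocone,4
A5381,SouthAmerican,ldm2,entoconulid,0
A5381,SouthAmerican,ldm2,metaconulid,2
A5381,SouthAmerican,udm2,carabelli,0
A5381,SouthAmerican,udm2,hypocone,4
BLZ_004,Bedouin,udm2,carabelli,0
BLZ_004,Bedouin,udm2,hypocone,3
BLZ_273,Bedouin,udm2,carabelli,0
BLZ_273,Bedouin,udm2,hypocone,3
BLZ_279,Bedouin,ldm2,entoconulid,0
BLZ_279,Bedouin,ldm2,metaconulid,0
BLZ_294,Bedouin,ldm2,entoconulid,0
BLZ_294,Bedouin,ldm2,metaconulid,0
BLZ_441,Bedouin,ldm2,entoconulid,0
BLZ_441,Bedouin,ldm2,metaconulid,0
Baka01,Baka,udm2,carabelli,0
Baka01,Baka,udm2,hypocone,3
Baka02,Baka,ldm2,entoconulid,0
Baka02,Baka,ldm2,metaconulid,0
Baka02,Baka,udm2,carabelli,0
Baka02,Baka,udm2,hypocone,4
Baka03,Baka,udm2,carabelli,0
Baka03,Baka,udm2,hypocone,4
Baka04,Baka,ldm2,entoconulid,0
Baka04,Baka,ldm2,metaconulid,0
Baka04,Baka,udm2,carabelli,0
Baka04,Baka,udm2,hypocone,4
Baka05,Baka,udm2,carabelli,0
Baka05,Baka,udm2,hypocone,4
Baka06,Baka,ldm2,entoconulid,0
Baka06,Baka,ldm2,metaconulid,0
Baka06,Baka,udm2,carabelli,0
Baka06,Baka,udm2,hypocone,4
Baka08,Baka,ldm2,entoconulid,0
Baka08,Baka,ldm2,metaconulid,0
Baka08,Baka,udm2,carabelli,0
Baka08,Baka,udm2,hypocone,4
Baka09,Baka,udm2,carabelli,0
Baka09,Baka,udm2,hypocone,4
Baka10,Baka,ldm2,entoconulid,0
Baka10,Baka,ldm2,metaconulid,0
Baka10,Baka,udm2,carabelli,0
Baka10,Baka,udm2,hypocone,4
Baka11,Baka,udm2,carabelli,0
Baka11,Baka,udm2,hypocone,4
Baka12,Baka,udm2,carabelli,0
Baka12,Baka,udm2,hypocone,4
Baka13,Baka,ldm2,entoconulid,0
Baka13,Baka,ldm2,metaconulid,0
Baka13,Baka,udm2,carabelli,0
Baka13,Baka,udm2,hypocone,4
Baka14,Baka,udm2,carabelli,0
Baka14,Baka,udm2,hypocone,4
Baka16,Baka,ldm2,entoconulid,0
Baka16,Baka,ldm2,metaconulid,0
Baka17,Baka,ldm2,entoconulid,0
Baka17,Baka,ldm2,metaconulid,0
Baka17,Baka,udm2,carabelli,0
Baka17,Baka,udm2,hypocone,4
Baka18,Baka,ldm2,entoconulid,0
Baka18,Baka,ldm2,metaconulid,0
Baka18,Baka,udm2,carabelli,0
Baka18,Baka,udm2,hypocone,4
Baka19,Baka,ldm2,entoconulid,0
Baka19,Baka,ldm2,metaconulid,0
Baka20,Baka,ldm2,entoconulid,0
Baka20,Baka,ldm2,metaconulid,0
Baka20,Baka,udm2,carabelli,0
Baka20,Baka,udm2,hypocone,4
Baka22,Baka,ldm2,entoconulid,0
Baka22,Baka,ldm2,metaconulid,0
Baka23,Baka,ldm2,entoconulid,0
Baka23,Baka,ldm2,metaconulid,0
Baka23,Baka,udm2,carabelli,0
Baka23,Baka,udm2,hypocone,4
Baka24,Baka,ldm2,entoconulid,0
Baka24,Baka,ldm2,metaconulid,0
Baka25,Baka,ldm2,entoconulid,0
Baka25,Baka,ldm2,metaconulid,0
Baka25,Baka,udm2,carabelli,0
Baka25,Baka,udm2,hypocone,4
Baka28,Baka,ldm2,entoconulid,0
Baka28,Baka,ldm2,metaconulid,0
Baka29,Baka,ldm2,entoconulid,0
Baka29,Baka,ldm2,metaconulid,0
Baka30,Baka,ldm2,entoconulid,0
Baka30,Baka,ldm2,metaconulid,0
Baka31,Baka,ldm2,entoconulid,0
Baka31,Baka,ldm2,metaconulid,0
Baka32,Baka,ldm2,entoconulid,0
Baka32,Baka,ldm2,metaconulid,0
Baka33,Baka,ldm2,entoconulid,0
Baka33,Baka,ldm2,metaconulid,0
Baka34,Baka,ldm2,entoconulid,0
Baka34,Baka,ldm2,metaconulid,0
Baka34,Baka,udm2,carabelli,0
Baka34,Baka,udm2,hypocone,4
Baka35,Baka,ldm2,entoconulid,0
Baka35,Baka,ldm2,metaconulid,0
Baka35,Baka,udm2,carabelli,5
Baka35,Baka,udm2,hypocone,4
Baka36,Baka,ldm2,entoconulid,0
Baka36,Baka,ldm2,metaconulid,0
Baka37,Baka,ldm2,entoconulid,0
Baka37,Baka,ldm2,metaconulid,2
Baka38,Baka,ldm2,entoconulid,0
Baka38,Baka,ldm2,metaconulid,2
Baka38,Baka,udm2,carabelli,5
Baka38,Baka,udm2,hypocone,4
Baka39,Baka,ldm2,entoconulid,0
Baka39,Baka,ldm2,metaconulid,2
Baka39,Baka,udm2,carabelli,5
Baka39,Baka,udm2,hypocone,4
Baka40,Baka,ldm2,entoconulid,0
Baka40,Baka,ldm2,metaconulid,2
Baka40,Baka,udm2,carabelli,5
Baka40,Baka,udm2,hypocone,4
Baka41,Baka,ldm2,entoconulid,3
Baka41,Baka,ldm2,metaconulid,2
Baka43,Baka,ldm2,entoconulid,3
Baka43,Baka,ldm2,metaconulid,2
Baka44,Baka,ldm2,entoconulid,3
Baka44,Baka,ldm2,metaconulid,2
Baka45,Baka,ldm2,entoconulid,3
Baka45,Baka,ldm2,metaconulid,2
C120,Egyptian,ldm2,entoconulid,0
C120,Egyptian,ldm2,metaconulid,0
C120,Egyptian,udm2,carabelli,0
C120,Egyptian,udm2,hypocone,3
C392,Egyptian,ldm2,entoconulid,0
C392,Egyptian,ldm2,metaconulid,0
C392,Egyptian,udm2,carabelli,0
C392,Egyptian,udm2,hypocone,3
CA_T19,European,ldm2,entoconulid,0
CA_T19,European,ldm2,metaconulid,0
CN101,Egyptian,ldm2,entoconulid,0
CN101,Egyptian,ldm2,metaconulid,0
CN141,Egyptian,udm2,carabelli,0
CN141,Egyptian,udm2,hypocone,4
CN17,Egyptian,udm2,carabelli,0
CN17,Egyptian,udm2,hypocone,4
CN233,Egyptian,ldm2,entoconulid,0
CN233,Egyptian,ldm2,metaconulid,0
CN26,Egyptian,ldm2,entoconulid,0
CN26,Egyptian,ldm2,metaconulid,2
CN26,Egyptian,udm2,carabelli,0
CN26,Egyptian,udm2,hypocone,4
CN61,Egyptian,ldm2,entoconulid,0
CN61,Egyptian,ldm2,metaconulid,2
CN61,Egyptian,udm2,carabelli,5
CN61,Egyptian,udm2,hypocone,4
Cs13,European,udm2,carabelli,0
Cs13,European,udm2,hypocone,3
Cs305,European,udm2,carabelli,0
Cs305,European,udm2,hypocone,3
Cs444,European,udm2,carabelli,0
Cs444,European,udm2,hypocone,3
E105,European,udm2,carabelli,0
E105,European,udm2,hypocone,3
E113,European,udm2,carabelli,0
E113,European,udm2,hypocone,3
E115,European,udm2,carabelli,0
E115,European,udm2,hypocone,3
E116,European,udm2,carabelli,0
E116,European,udm2,hypocone,3
E319,European,udm2,carabelli,0
E319,European,udm2,hypocone,3
E322,European,udm2,carabelli,0
E322,European,udm2,hypocone,3
E429,European,udm2,carabelli,0
E429,European,udm2,hypocone,3
E44,European,udm2,carabelli,0
E44,European,udm2,hypocone,3
E513,European,udm2,carabelli,0
E513,European,udm2,hypocone,4
E52,European,udm2,carabelli,0
E52,European,udm2,hypocone,4
E549,European,udm2,carabelli,0
E549,European,udm2,hypocone,4
E57,European,udm2,carabelli,0
E57,European,udm2,hypocone,4
E75,European,udm2,carabelli,0
E75,European,udm2,hypocone,4
E93,European,udm2,carabelli,0
E93,European,udm2,hypocone,4
E96,European,udm2,carabelli,0
E96,European,udm2,hypocone,4
EH-U21,European,ldm2,entoconulid,0
EH-U21,European,ldm2,metaconulid,0
EH-U56,European,ldm2,entoconulid,0
EH-U56,European,ldm2,metaconulid,0
EH-U57,European,ldm2,entoconulid,0
EH-U57,European,ldm2,metaconulid,0
FI3528,SoutheastAsian,ldm2,entoconulid,0
FI3528,SoutheastAsian,ldm2,metaconulid,0
FI3528,SoutheastAsian,udm2,carabelli,0
FI3528,SoutheastAsian,udm2,hypocone,3
Guid_T49,European,ldm2,entoconulid,0
Guid_T49,European,ldm2,metaconulid,0
I9664,SoutheastAsian,ldm2,entoconulid,0
I9664,SoutheastAsian,ldm2,metaconulid,0
I9664,SoutheastAsian,udm2,carabelli,0
I9664,SoutheastAsian,udm2,hypocone,3
I9665,SoutheastAsian,ldm2,entoconulid,0
I9665,SoutheastAsian,ldm2,metaconulid,2
Med1_Batch1,European,ldm2,entoconulid,0
Med1_Batch1,European,ldm2,metaconulid,0
NZ_3108,SoutheastAsian,udm2,carabelli,0
NZ_3108,SoutheastAsian,udm2,hypocone,4
NZ_3125-11,SoutheastAsian,udm2,carabelli,0
NZ_3125-11,SoutheastAsian,udm2,hypocone,4
Nr115,European,udm2,carabelli,0
Nr115,European,udm2,hypocone,4
Nr116,European,udm2,carabelli,0
Nr116,European,udm2,hypocone,4
Nr396,European,udm2,carabelli,0
Nr396,European,udm2,hypocone,4
Nr75,European,udm2,carabelli,5
Nr75,European,udm2,hypocone,4
PM,European,ldm2,entoconulid,0
PM,European,ldm2,metaconulid,0
RCEH036,Bedouin,ldm2,entoconulid,3
RCEH036,Bedouin,ldm2,metaconulid,2
SI3256,SoutheastAsian,udm2,carabelli,0
SI3256,SoutheastAsian,udm2,hypocone,4
Tb36,European,ldm2,entoconulid,0
Tb36,European,ldm2,metaconulid,0
Tb37,European,ldm2,entoconulid,0
Tb37,European,ldm2,metaconulid,0
Tb44R,European,ldm2,entoconulid,0
Tb44R,European,ldm2,metaconulid,2
Tb49,European,ldm2,entoconulid,0
Tb49,European,ldm2,metaconulid,2
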