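id,population,sex,wear_u,wear_l
Baka01,Baka,f,3,
Baka02,Baka,f,3,3
Baka03,Baka,f,3,
Baka04,Baka,f,3,3
Baka05,Baka,m,3,
Baka06,Baka,f,3,3
Baka08,Baka,f,3,3
Baka09,Baka,f,3,
Baka10,Baka,f,3,3
Baka11,Baka,m,3,
Baka12,Baka,f,3,
Baka13,Baka,f,3,3
Baka14,Baka,f,3,
Baka16,Baka,m,,3
Baka17,Baka,m,3,3
Baka18,Baka,m,3,4
Baka19,Baka,f,,3
Baka20,Baka,f,3,3
Baka22,Baka,f,,3
Baka23,Baka,m,3,3
Baka24,Baka,f,,3
Baka25,Baka,m,3,3
Baka28,Baka,m,,3
Baka29,Baka,f,,3
Baka30,Baka,m,,3
Baka31,Baka,f,,3
Baka32,Baka,f,,3
Baka33,Baka,f,,3
Baka34,Baka,m,3,3
Baka35,Baka,m,5,3
Baka36,Baka,m,,3
Baka37,Baka,m,,3
Baka38,Baka,m,3,3
Baka39,Baka,m,3,3
Baka40,Baka,m,3,2
Baka41,Baka,f,,3
Baka43,Baka,m,,2
Baka44,Baka,m,,5
Baka45,Baka,m,,5
E44,European,?,1,
E52,European,?,1,
E57,European,?,1,
E75,European,?,1,
E93,European,?,1,
E96,European,?,1,
E105,European,?,1,
E113,European,?,1,
E115,European,?,1,
E116,European,?,1,
E319,European,?,1,
E322,European,?,1,
E429,European,?,1,
E513,European,?,1,
E549,European,?,1,
Nr75,European,?,1,
Nr115,European,?,1,
Nr116,European,?,1,
Nr396,European,?,1,
Cs13,European,?,2,
Cs305,European,?,2,
Cs444,European,?,1,
EH-U21,European,?,,1
EH-U56,European,?,,1
EH-U57,European,?,,1
CA_T19,European,?,,1
Med1_Batch1,European,?,,1
Guid_T49,European,?,,1
PM,European,?,,1
Tb36,European,?,,1
Tb37,European,?,,1
Tb44R,European,?,,1
Tb49,European,?,,1
BLZ_004,Bedouin,?,3,
BLZ_273,Bedouin,?,3,
BLZ_279,Bedouin,?,,1
BLZ_294,Bedouin,?,,1
BLZ_441,Bedouin,?,,1
RCEH036,Bedouin,?,,2
A5380,SouthAmerican,?,3,2
A5381,SouthAmerican,?,3,3
A113,Egyptian,?,,4
C120,Egyptian,?,3,3
C392,Egyptian,m,4,2
CN101,Egyptian,?,,2
CN141,Egyptian,?,3,
CN17,Egyptian,?,3,
CN233,Egyptian,?,,2
CN26,Egyptian,?,3,3
CN61,Egyptian,?,3,3
SI3256,SoutheastAsian,?,1,
FI3528,SoutheastAsian,?,2,3
I9664,SoutheastAsian,?,1,1
I9665,SoutheastAsian,?,,4
NZ_3108,SoutheastAsian,?,3,
NZ_3125-11,SoutheastAsian,?,3,
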