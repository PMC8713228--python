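factor,category,count_positive,count_negative
Sex,Female,144,178
Sex,Male,53,37
Age,<45 yrs,111,95
Age,≥45 yrs,86,120
TD,<0.7 cm,18,74
TD,0.7-1.0 cm,37,55
TD,1.0-1.5 cm,53,62
TD,1.5-2.0 cm,35,16
TD,≥2.0 cm,54,8
CI,Y,61,20
CI,N,136,195
Multifocality,Y,13,9
Multifocality,N,184,206
TL,Upper pole,26,48
TL,Middle pole,106,111
TL,Lower pole,57,45
TL,Isthmus,8,11
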