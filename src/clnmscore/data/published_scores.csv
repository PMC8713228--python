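factor,category,score_positive,score_negative
Sex,Female,8.6,9.2
Sex,Male,4.3,2.4
Age,<45 yrs,7.5,6.5
Age,≥45 yrs,6.4,7.5
TD,<0.7 cm,-0.4,5.4
TD,0.7-1.0 cm,2.7,4.1
TD,1.0-1.5 cm,4.3,4.6
TD,1.5-2.0 cm,2.5,-1.3
TD,≥2.0 cm,4.4,-4.3
CI,Y,4.9,-0.3
CI,N,8.4,9.6
Multifocality,Y,-1.8,-3.8
Multifocality,N,9.7,9.8
TL,Upper pole,1.2,3.5
TL,Middle pole,7.3,7.1
TL,Lower pole,4.6,3.2
TL,Isthmus,-3.9,-2.9
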