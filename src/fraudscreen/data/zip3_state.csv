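zip3,state
010,MA
018,MA
021,MA
022,MA
027,MA
028,RI
029,RI
030,NH
034,NH
038,NH
039,ME
044,ME
049,ME
050,VT
054,VT
059,VT
060,CT
064,CT
069,CT
070,NJ
079,NJ
089,NJ
100,NY
124,NY
149,NY
150,PA
173,PA
191,PA
196,PA
197,DE
198,DE
199,DE
200,DC
202,DC
203,DC
205,DC
206,MD
212,MD
219,MD
220,VA
233,VA
246,VA
247,WV
257,WV
268,WV
270,NC
279,NC
289,NC
290,SC
294,SC
299,SC
300,GA
303,GA
309,GA
319,GA
320,FL
331,FL
334,FL
349,FL
350,AL
359,AL
369,AL
370,TN
377,TN
385,TN
386,MS
391,MS
397,MS
400,KY
413,KY
427,KY
430,OH
441,OH
444,OH
459,OH
460,IN
469,IN
479,IN
480,MI
489,MI
499,MI
500,IA
514,IA
528,IA
530,WI
539,WI
549,WI
550,MN
558,MN
567,MN
570,SD
573,SD
577,SD
580,ND
584,ND
588,ND
590,MT
594,MT
599,MT
600,IL
606,IL
614,IL
629,IL
630,MO
644,MO
658,MO
660,KS
669,KS
679,KS
680,NE
686,NE
693,NE
700,LA
707,LA
714,LA
716,AR
722,AR
729,AR
730,OK
739,OK
749,OK
750,TX
774,TX
799,TX
800,CO
802,CO
808,CO
816,CO
820,WY
825,WY
831,WY
832,ID
835,ID
838,ID
840,UT
843,UT
847,UT
850,AZ
852,AZ
857,AZ
865,AZ
870,NM
877,NM
884,NM
889,NV
893,NV
898,NV
900,CA
930,CA
961,CA
967,HI
968,HI
970,OR
974,OR
979,OR
980,WA
981,WA
987,WA
994,WA
995,AK
997,AK
999,AK
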