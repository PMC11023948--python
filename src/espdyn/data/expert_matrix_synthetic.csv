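code,label,I1,P1,R1,R2,R3,C1
11100,Continuous urban fabric (S.L. > 80%),5,5,5,5,5,10
11210,Discontinuous dense urban fabric,10,5,5,10,5,15
11220,Discontinuous medium density urban fabric,15,5,10,15,10,20
11230,Discontinuous low density urban fabric,20,5,15,20,15,25
11240,Discontinuous very low density urban fabric,25,5,20,25,20,30
11300,Isolated structures,10,5,10,10,10,10
12100,"Industrial, commercial, public, military and private units",5,5,5,5,5,5
12210,Fast transit roads and associated land,5,5,5,5,5,30
12220,Other roads and associated land,5,5,5,5,5,25
12230,Railways and associated land,10,5,5,5,5,20
12300,Port areas,5,5,5,5,5,15
12400,Airports,10,5,5,5,5,5
13100,Mineral extraction and dump sites,5,5,5,5,5,5
13300,Construction sites,5,5,5,5,5,5
13400,Land without current use,15,5,10,10,10,10
14100,Green urban areas,40,10,25,40,30,60
14200,Sports and leisure facilities,25,10,15,25,20,55
21000,Arable land (annual crops),30,5,15,25,20,25
22000,Permanent crops,35,5,20,30,25,30
23000,Pastures,45,15,30,40,35,40
24000,Complex and mixed cultivation patterns,40,10,25,35,30,35
25000,Orchards,35,5,20,30,25,30
31000,Forests,70,60,55,85,65,85
32000,Herbaceous vegetation associations,55,25,35,55,45,55
33000,Open spaces with little or no vegetation,30,10,10,15,17,50
40000,Wetlands,85,35,75,70,90,60
50000,Water,75,80,60,55,75,80
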