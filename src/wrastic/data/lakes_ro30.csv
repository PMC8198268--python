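lake_id,name,area_ha,protected,morphologic_unit,W,R,A,a,S,T,I,C,slope,aspect,permeability,state
1,Lake Voila,217,yes,Fagaras Depression,0,5,3,2,1,1,0,2,1,5,3,semi_degraded
2,Lake Snagov,422,yes,Snagov Plain,3,5,3,1,2,4,1,2,1,3,1,semi_degraded
3,Lake Vacaresti,126,no,Targoviste Plain,3,5,5,2,1,3,3,4,1,3,1,degraded
4,Lake Vidraru,803,yes,Lovistei Mountains,2,5,1,1,2,4,0,1,4,5,1,semi_degraded
5,Lake Tau,78,yes,Cindrel Mountains,2,5,1,1,1,4,0,1,4,5,1,semi_degraded
6,Lake Firiza (Stramtori),104,no,Ignis Mountains,2,5,1,1,2,4,1,1,3,5,1,semi_degraded
7,Lake Surduc,352,yes,Lugojului Hills,3,5,3,2,2,3,0,1,3,3,1,semi_degraded
8,Lake Taut,176,yes,Tauti Depression,3,5,3,2,2,3,0,1,3,3,1,semi_degraded
9,Lake Bezid,162,yes,Tarnavelor Sub-Carpathian Region,0,5,1,4,1,3,1,1,3,5,1,semi_degraded
10,Lake Lugasu,325,yes,Vad-Oradea Depression,3,5,3,2,1,5,0,4,1,5,1,semi_degraded
11,Lake Stiucilor,31,yes,Sicului Hills,2,5,5,3,1,4,0,3,3,3,1,semi_degraded
12,Lake Varsolt,324,no,Simleu Depression,3,5,5,1,1,4,1,2,1,5,1,semi_degraded
13,Lake Zanoaga Mare,6,yes,Retezat Mountains,0,2,1,1,1,1,0,2,3,3,1,natural
14,Lake Oltina,1958,yes,Oltina Plateau,3,5,5,1,2,3,1,4,3,5,1,semi_degraded
15,Lake Siutghiol,1756,yes,Istria Plateau,2,5,3,1,2,5,3,4,2,3,1,semi_degraded
16,Lake Rosu,165,yes,Hasmas Mountains,2,5,1,1,1,1,0,1,4,5,1,semi_degraded
17,Lake Lala,44,yes,Rodna Mountains,3,2,1,1,1,1,0,1,4,3,1,natural
18,Lake Bistret,409,yes,Bistretului Alluvial Plain,3,2,1,1,1,4,1,5,1,3,5,semi_degraded
19,Lake Potcoava,90,yes,Danube Delta,2,1,1,1,2,0,0,1,1,3,1,natural
20,Lake Merhei,1385,yes,Danube Delta,0,1,1,1,2,0,0,1,1,3,1,natural
21,Lake Calimanesti,801,yes,Siretului Plain,2,5,5,1,2,3,3,2,1,5,1,semi_degraded
22,Lake Siriu,195,yes,Podu Calului Mountains,0,5,1,1,1,4,3,1,4,5,1,semi_degraded
23,Lake Brates,2199,yes,Brates Alluvial Plain,3,5,5,1,2,5,3,5,1,5,5,degraded
24,Lake Poiana Uzului,265,no,Slanicului Hills,2,5,1,1,2,3,1,1,3,5,5,semi_degraded
25,Lake Amara,700,yes,Buzaului Alluvial Plain,3,5,5,1,2,4,0,4,1,5,1,semi_degraded
26,Lake Razim,39569,yes,Danube Delta,0,5,1,1,4,4,0,4,1,3,1,semi_degraded
27,Lake Solesti,374,no,Repedea-Zapodeni Plateau,3,5,5,2,1,4,0,3,3,5,1,semi_degraded
28,Lake Bratul Dunarea Veche,186,yes,Drobeta-Bala Corridor,1,1,1,2,1,4,5,1,1,5,1,semi_degraded
29,Lake Izvorul Muntelui,2843,yes,Ceahlau Mountains,2,5,1,1,2,4,0,1,3,3,1,semi_degraded
30,Lake Stanca Costesti,4954,yes,Prut Corridor,0,5,3,1,1,0,0,4,1,3,1,semi_degraded
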