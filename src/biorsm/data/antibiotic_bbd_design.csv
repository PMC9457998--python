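run_id,pH,OLR,ANT,CIP,CIP_pred,ENRO,ENRO_pred,COD,COD_pred
1,7,2,10,69,70,68,68,80,80
2,7,6,10,68,68,66,67,82,82
3,7,4,55,77,78,74,76,76,75
4,8,2,55,75,74,76,74,75,74
5,7,4,55,78,78,75,76,74,75
6,6,2,55,76,77,78,78,76,77
7,8,4,10,69,69,70,70,80,80
8,7,2,100,83,83,86,85,68,68
9,7,4,55,78,78,74,76,76,75
10,6,4,10,69,68,65,64,83,82
11,8,4,100,79,80,85,86,67,68
12,8,6,55,75,75,84,81,78,77
13,6,4,100,86,86,86,85,68,68
14,7,6,100,85,84,85,86,69,69
15,6,6,55,75,76,73,71,75,76
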