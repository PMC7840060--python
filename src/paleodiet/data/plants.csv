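id,phase,species,part,pctN,d15N,pctC,d13C,CN
PAbot1,MBA_FBA,Vicia faba,seed,4.7,2.6,44.9,-23.1,11.2
PAbot2,MBA_FBA,Hordeum vulgare,seed,2.5,3.0,57.8,-24.8,27.2
PAbot3,FBA,Panicum miliaceum,seed,3.6,5.5,51.7,-9.4,16.9
PAbot4,MBA_FBA,Hordeum vulgare,seed,2.0,3.6,61.0,-24.9,35.1
PAbot5,MBA_FBA,Hordeum vulgare,seed,2.0,4.0,55.6,-24.2,31.9
PAbot6,MBA_FBA,Fabaceae,seed,4.5,3.3,50.6,-15.3,13.1
PAbot7,MBA_FBA,Fabaceae,seed,7.7,1.8,56.3,-23.9,8.5
PAbot8,FBA,Fabaceae,seed,6.3,1.1,53.7,-24.2,10.0
PAbot9,EBA,Triticum sp,seed,3.0,4.4,60.1,-27.0,23.5
PAbot10,EBA,Triticum sp,seed,3.0,3.7,60.6,-26.2,23.3
PAbot11,EBA,Triticum sp,seed,1.9,3.6,53.8,-23.9,32.4
VE1,FBA,Triticum dicoccum,seed,1.7,2.1,48.7,-24.7,33.3
VE2,FBA,Triticum dicoccum,seed,2.8,3.4,43.9,-23.6,18.5
VE3,FBA,Triticum dicoccum,seed,1.9,6.3,34.4,-23.6,21.5
VE4,FBA,Triticum dicoccum,seed,3.0,3.1,54.7,-24.4,21.5
VE5,FBA,Hordeum vulgare,seed,6.1,2.2,62.1,-24.3,12.0
VE6,FBA,Hordeum vulgare,seed,,,,,
VE7,FBA,Panicum miliaceum,seed,3.0,6.1,52.7,-10.8,20.4
VE8,FBA,Vicia sp,seed,5.6,2.8,61.6,-26.1,12.9
VE9,FBA,Setaria italica,seed,1.1,6.4,17.7,-10.5,19.2
VE10,FBA,Vicia sp,seed,3.1,6.7,52.1,-24.1,19.6
VE11,FBA,Vicia sp,seed,1.6,6.5,46.4,-24.5,34.0
VE12,FBA,Vicia sp,seed,2.0,5.3,64.6,-26.5,37.1
VE13,FBA,Triticum monococcum/dicoccum,chaff,0.8,4.6,62.1,-25.4,87.4
VE14,FBA,Triticum monococcum/dicoccum,chaff,0.7,2.5,59.4,-25.8,100.4
VE15,FBA,Setaria/Panicum,seed,3.0,5.4,61.0,-10.1,23.9
VE16,FBA,Setaria/Panicum,seed,2.7,5.3,61.8,-10.5,26.3
VE17,FBA,Triticum sp,seed,2.1,2.6,54.0,-23.5,29.4
VE18,FBA,Triticum sp,seed,2.6,5.7,53.1,-24.5,24.1
VE19,FBA,Triticum sp,chaff,0.5,2.7,60.1,-25.3,133.3
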