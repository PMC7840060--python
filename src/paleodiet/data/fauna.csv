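id,phase,site,species,element,pctN,d15N,pctC,d13C,pctS,d34S,CN,CS,NS
BANF1,EBA,LaBarmaz,Sus domesticus,humerus,13.7,5.8,37.7,-21.0,,,3.2,,
BANF2,EBA,LaBarmaz,Ovis aries/Capra hircus,tibia,3.3,5.3,9.5,-21.2,0.06,1.8,3.4,399.0,117.4
BANF3,EBA,LaBarmaz,Sus domesticus,humerus,0.1,,1.5,,0.05,2.9,18.6,88.3,4.8
BANF5,EBA,LaBarmaz,Ovis aries/Capra hircus,tibia,14.6,5.3,39.7,-21.0,0.20,4.3,3.2,532.2,168.5
BANF6,EBA,LaBarmaz,Bos taurus,talus,10.3,4.8,28.0,-21.0,0.13,3.5,3.2,565.8,179.5
BANF7,EBA,LaBarmaz,Bos taurus,talus,9.9,4.7,27.3,-21.2,0.12,3.8,3.2,588.4,182.8
BANF8,EBA,LaBarmaz,Bos taurus,talus,14.9,3.9,40.6,-21.1,0.20,5.2,3.2,548.2,173.2
RCV4,MBA,Rances,Bos taurus,humerus,14.3,5.9,39.2,-21.4,0.20,8.4,3.2,403.3,127.1
RCV10,MBA,Rances,Sus domesticus,mandible,12.7,8.7,34.9,-20.0,0.18,8.7,3.2,431.1,136.2
TO1,FBA,ChensTougues,Ovis aries,radius,15.1,6.5,41.1,-21.6,0.27,3.1,3.2,389.9,122.3
TO2,FBA,ChensTougues,Bos taurus,radius,14.7,6.6,40.1,-21.4,0.25,4.7,3.2,339.0,106.2
TO4,FBA,ChensTougues,Cervus elaphus,radius,15.2,5.9,41.7,-21.3,0.28,1.8,3.2,373.4,116.5
TO5,FBA,ChensTougues,Capra hircus,ulna,14.2,3.7,39.1,-21.4,0.31,3.7,3.2,331.1,102.1
TO7,FBA,ChensTougues,Sus domesticus,humerus,14.9,8.5,41.0,-20.3,0.29,3.5,3.2,298.5,91.7
TO8,FBA,ChensTougues,Sus domesticus,humerus,15.0,6.4,41.8,-20.4,0.33,4.4,3.3,386.2,121.1
TO9,FBA,ChensTougues,Sus domesticus,mandible,14.2,6.3,39.6,-21.0,0.35,3.2,3.3,335.2,104.5
TO11,FBA,ChensTougues,Bos taurus,humerus,14.6,2.7,40.0,-22.0,0.27,0.7,3.2,403.3,127.1
TO13,FBA,ChensTougues,Ovis aries,tibia,14.2,7.0,39.2,-20.7,0.31,4.2,3.2,431.1,136.2
CHIN1,FBA,Chindrieux,Esox lucius,vertebra,14.9,10.7,45.3,-21.5,0.60,-1.8,3.5,199.1,56.4
CHIN2,FBA,Chindrieux,Esox lucius,vertebra,14.5,9.8,44.2,-23.4,0.55,-5.7,3.5,213.0,60.3
CHIN3,FBA,Chindrieux,Esox lucius,vertebra,15.1,10.4,45.3,-23.8,0.61,-5.2,3.5,198.2,57.0
CHIN4,FBA,Chindrieux,Esox lucius,hyomandibular,1.5,10.3,7.0,-24.1,0.21,-6.7,5.4,89.2,16.5
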