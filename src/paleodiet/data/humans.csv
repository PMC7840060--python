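id,site,burial,grave_goods,element,tooth,sex,age_class,bone_pctN,bone_d15N,bone_pctC,bone_d13C,bone_CN,bone_pctS,bone_d34S,bone_CS,bone_NS,dent_pctN,dent_d15N,dent_pctC,dent_d13C,enamel_carbonate,enamel_d13C
BA3,LaBarmaz,N3,present,ulna R,M2 R,F,adult,14.1,8.3,38.5,-20.5,3.2,0.21,3.5,485.2,153.0,15.9,9.1,42.8,-20.1,4.16,-14.1
BA5,LaBarmaz,N5,absent,ulna L,M2 R,M,adult,15.1,8.4,40.9,-20.4,3.2,0.19,-2.6,570.4,181.1,16.4,8.6,45.2,-20.4,2.73,-15.1
BA6a/b,LaBarmaz,N6a/N6b,not_defined,ulna L,M2 R,F,adult,12.8,7.8,35.9,-20.1,3.3,0.19,2.0,488.5,150.3,16.9,8.6,45.4,-20.1,3.59,-13.8
BA6,LaBarmaz,N6,present,ulna L,M2 R,F,adult,14.9,8.4,40.4,-20.4,3.2,0.18,1.8,580.6,183.9,15.0,8.9,42.1,-20.7,3.16,-14.3
BA22,LaBarmaz,N22,present,ulna L,M2 R,M,adult,15.1,8.8,44.6,-20.8,3.4,0.23,0.8,510.0,148.6,16.1,9.6,43.2,-20.8,2.50,-15.4
BA23,LaBarmaz,N23,absent,tibia R,M2 R,M,adult,16.0,10.1,47.2,-20.5,3.4,0.23,1.6,554.8,161.5,16.0,11.8,43.5,-20.4,3.04,-14.5
BA25,LaBarmaz,N25,absent,ulna L,M2 R,M,adult,15.1,8.9,45.2,-20.8,3.5,0.26,1.0,470.2,135.4,16.0,8.8,43.5,-20.8,2.54,-14.3
BA26,LaBarmaz,N26,absent,ulna L,M2 R,M,adult,15.4,10.0,46.1,-20.5,3.5,0.24,-0.8,514.6,148.2,16.6,10.0,44.7,-20.3,3.01,-13.7
BA28,LaBarmaz,N28,absent,humerus R,M2 R,F,adult,15.9,8.0,47.7,-20.9,3.5,0.26,2.3,484.8,139.4,17.0,7.9,45.7,-21.1,2.87,-15.0
BA42,LaBarmaz,N42,present,ulna L,M2 R,M,young_adult,16.7,7.7,49.7,-21.2,3.5,0.25,0.8,526.2,151.7,16.6,8.5,45.7,-21.1,3.29,-14.1
BA50,LaBarmaz,T50,absent,ulna L,M2 R,F,adult,14.0,9.0,41.8,-20.2,3.5,0.22,4.2,493.7,142.6,16.2,9.8,46.5,-20.0,2.70,-12.9
BA53,LaBarmaz,N53,absent,tibia R,,M,adult,15.5,8.2,46.6,-20.9,3.5,0.26,0.8,475.1,136.2,,,,,,
ZHB,LaBarmaz,ZHB,present,ulna L,M2 R,M,adult,13.1,8.3,37.0,-20.6,3.3,0.19,4.1,505.6,154.6,16.2,8.1,44.5,-21.1,2.98,-14.8
VF1,Vufflens,VF 94/st 1 ind 1,present,ulna R,M2 R,F,adult,14.9,9.0,44.5,-20.4,3.5,0.25,3.7,479.4,137.9,16.5,8.8,44.6,-20.8,1.47,-13.7
VF2,Vufflens,VF 94/st 1 ind 2,present,fibula,M2 R,M,young_adult,13.8,9.6,41.8,-20.4,3.5,0.22,3.1,505.1,143.3,16.5,8.8,44.3,-20.6,2.29,-13.7
VF3,Vufflens,VF 95/st 4 ind 1,present,humerus R,M2 L,F,adult,14.5,9.5,43.3,-20.3,3.5,0.28,4.4,410.1,118.4,16.6,10.1,44.7,-20.6,2.82,-13.7
VF4,Vufflens,VF 95/st 4 ind 2,not_defined,humerus L,M2 R,I,child,14.6,8.8,43.8,-20.3,3.5,0.25,3.8,457.6,131.0,12.3,9.5,34.1,-20.5,2.77,-13.1
VF5,Vufflens,VF 95/st 4 ind 3,not_defined,ulna R,M2 L,F,young_adult,14.2,10.0,42.9,-20.9,3.5,0.24,2.0,477.0,135.6,14.4,10.3,41.1,-21.5,2.63,-13.7
VF6,Vufflens,VF 95/st 4 ind 4,not_defined,ulna L,C sup R,I,child,13.4,9.5,42.1,-20.9,3.7,0.25,3.6,445.6,122.2,16.0,10.2,43.4,-20.5,3.33,-13.0
VF7,Vufflens,VF 95/st 4 ind 5,present,ulna R,M2 R,F,adolescent,14.3,8.6,43.0,-20.5,3.5,0.26,2.1,442.9,126.6,15.3,8.7,43.0,-21.0,2.30,-13.4
VF8,Vufflens,VF 95/st 4 ind 6,present,ulna L,M2 L,F,adult,14.2,8.7,42.9,-20.5,3.5,0.27,3.7,422.2,120.3,16.1,8.8,44.0,-20.7,2.23,-13.6
VF9,Vufflens,VF 95/st 9,present,radius L,M2 L,M,adult,13.0,9.8,39.7,-20.5,3.5,0.27,2.6,393.6,111.3,12.8,10.4,35.9,-20.5,3.36,-12.8
VF10,Vufflens,VF 95/st 10,present,radius,M2 L,I,child,14.7,8.8,44.4,-20.6,3.5,0.22,2.8,533.0,152.1,16.2,9.3,43.5,-20.8,1.75,-13.6
VF11,Vufflens,VF 95/st 11,absent,radius L,M2 R,M,adolescent,14.8,8.9,44.5,-20.4,3.5,0.24,2.9,483.1,138.1,15.6,9.7,42.7,-20.4,2.27,-13.9
VF12,Vufflens,VF 95/st 14,absent,ulna R,M2 L,M,young_adult,14.7,8.4,44.0,-20.5,3.5,0.25,2.8,474.4,136.2,16.1,8.5,44.4,-21.2,3.38,-13.8
LaC1,Tolochenaz,st. 1052,present,radius R,M2 L,M,adult,10.2,8.6,35.8,-17.6,4.1,0.13,7.4,722.9,176.3,16.1,9.6,43.7,-20.3,2.39,-13.3
LaC2,Tolochenaz,st. 1061,present,radius R,M2 R,F,adult,14.8,7.3,44.5,-18.0,3.5,0.19,2.8,609.0,174.6,16.1,7.3,43.6,-18.3,2.57,-10.8
LaC3,Tolochenaz,st. 1074,present,tibia R,M1 L,I,adult,10.8,8.6,30.5,-18.5,3.3,,,,,15.5,8.5,42.1,-16.7,2.47,-9.3
LaC4,Tolochenaz,st. 1111,present,ulna L,PM1 L,M,adult,6.4,8.6,18.2,-18.2,3.3,0.12,6.7,410.8,124.2,16.4,8.4,44.1,-17.1,2.21,-9.1
LaC5,Tolochenaz,st. 1057,absent,ulna R,M2 R,I,child,12.9,7.5,34.8,-18.4,3.2,0.17,5.7,530.3,168.9,16.1,8.0,44.1,-18.3,4.15,-10.6
LaC6,Tolochenaz,st. 1080,present,humerus,I2 R,I,child,11.4,7.7,31.1,-18.4,3.2,0.16,4.6,515.1,162.3,14.9,9.4,40.8,-17.8,3.22,-10.4
LaC7,Tolochenaz,st. 1018,present,clavicle R,I2 R,I,child,14.5,8.1,39.0,-18.3,3.1,0.19,4.0,542.4,173.4,15.1,9.9,40.7,-16.4,2.99,-9.4
LaC8,Tolochenaz,st. 1070,present,femur L,,I,child,13.8,8.0,37.8,-19.1,3.2,0.18,5.0,545.6,170.8,,,,,,
LaC9,Tolochenaz,st. 1083,present,tibia R,,I,adult,13.0,7.6,35.2,-17.6,3.2,0.16,4.1,594.1,188.2,,,,,,
LaC10,Tolochenaz,st. 1071,present,femur R,,I,adult,1.0,,3.9,,,,,,,,,,,,
LeB1,Tolochenaz,tb XXIV,not_defined,femur L,M2 L,unknown,unknown,14.6,9.2,44.1,-20.5,3.5,0.23,0.9,514.5,146.9,15.4,9.7,41.6,-20.3,1.46,-14.4
LeB2,Tolochenaz,tb IX-X,present,femur R,,M,unknown,10.4,8.3,31.8,-17.2,3.5,0.20,1.3,423.8,120.0,,,,,,
LeB3,Tolochenaz,,not_defined,femur R,,unknown,unknown,15.6,9.7,46.7,-20.4,3.5,0.20,2.9,604.4,173.7,,,,,,
LeB4,Tolochenaz,tb I,not_defined,femur R,M2 R,unknown,unknown,13.8,7.2,42.1,-18.2,3.6,0.22,1.2,505.7,142.6,13.8,7.5,38.9,-17.7,3.33,-10.1
LeB5,Tolochenaz,tb III,present,femur L,M2 L,unknown,unknown,14.1,8.4,42.3,-17.2,3.5,0.20,8.9,556.4,159.8,14.9,10.1,41.2,-17.1,2.70,-9.9
LeB6,Tolochenaz,,not_defined,humerus L,M2 R,unknown,unknown,15.6,8.6,47.0,-17.5,3.5,0.19,6.7,638.9,182.5,15.6,8.5,42.1,-17.4,1.53,-10.3
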