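species,family,tissue,n,d18O_co3_mean,d18O_co3_sd,d18O_co3_min,d18O_co3_max,d13C_mean,d13C_sd,d13C_min,d13C_max
Arvicola terrestris,arvicolid,incisor,10,26.8,1.4,24.9,28.8,-17.7,0.6,-18.5,-16.7
Myodes glareolus,arvicolid,incisor,10,27.2,1.8,24.7,31.4,-16.2,0.7,-17.3,-15.1
Microtus agrestis,arvicolid,incisor,10,27.3,1.1,26.0,28.8,-19.7,0.6,-20.5,-18.6
Microtus arvalis,arvicolid,incisor,10,27.3,1.2,25.4,29.2,-18.8,1.4,-20.8,-16.8
Apodemus sylvaticus,murid,incisor,10,27.9,1.0,26.0,29.1,-15.9,1.7,-17.8,-12.4
Mus musculus,murid,incisor,10,28.3,1.0,26.4,29.7,-12.1,5.3,-17.4,-4.7
Rattus norvegicus,murid,incisor,10,29.0,0.7,27.8,29.9,-9.6,3.4,-14.7,-4.5
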