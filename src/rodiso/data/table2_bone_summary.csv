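species,family,tissue,n,d18O_co3_mean,d18O_co3_sd,d18O_co3_min,d18O_co3_max,d13C_mean,d13C_sd,d13C_min,d13C_max
Arvicola terrestris,arvicolid,bone,5,25.6,1.2,24.6,27.7,-17.8,0.9,-19.0,-16.8
Myodes glareolus,arvicolid,bone,5,25.7,1.4,24.0,27.3,-17.7,0.4,-18.3,-17.3
Microtus agrestis,arvicolid,bone,5,24.6,1.3,23.1,26.4,-19.5,0.6,-20.0,-18.5
Microtus arvalis,arvicolid,bone,5,26.6,1.3,24.8,27.9,-18.4,0.8,-19.5,-17.6
Apodemus sylvaticus,murid,bone,5,25.8,0.8,24.6,26.6,-16.4,1.3,-17.3,-14.1
Mus musculus,murid,bone,5,28.2,1.6,25.5,29.5,-11.6,5.5,-16.8,-5.0
Rattus norvegicus,murid,bone,5,25.8,1.0,24.7,26.7,-7.9,2.2,-10.7,-5.8
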