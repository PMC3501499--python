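species,n_sub,count,is_lower_bound
Arvicola terrestris,2,801,0
Arvicola terrestris,3,918,0
Arvicola terrestris,4,963,0
Arvicola terrestris,5,984,0
Arvicola terrestris,6,990,1
Arvicola terrestris,7,990,1
Arvicola terrestris,8,990,1
Arvicola terrestris,9,990,1
Myodes glareolus,2,819,0
Myodes glareolus,3,918,0
Myodes glareolus,4,951,0
Myodes glareolus,5,970,0
Myodes glareolus,6,981,0
Myodes glareolus,7,990,1
Myodes glareolus,8,990,1
Myodes glareolus,9,990,1
Microtus agrestis,2,831,0
Microtus agrestis,3,911,0
Microtus agrestis,4,957,0
Microtus agrestis,5,982,0
Microtus agrestis,6,990,0
Microtus agrestis,7,990,1
Microtus agrestis,8,990,1
Microtus agrestis,9,990,1
Microtus arvalis,2,802,0
Microtus arvalis,3,909,0
Microtus arvalis,4,950,0
Microtus arvalis,5,971,0
Microtus arvalis,6,983,0
Microtus arvalis,7,990,1
Microtus arvalis,8,990,1
Microtus arvalis,9,990,1
Apodemus sylvaticus,2,829,0
Apodemus sylvaticus,3,894,0
Apodemus sylvaticus,4,955,0
Apodemus sylvaticus,5,978,0
Apodemus sylvaticus,6,986,0
Apodemus sylvaticus,7,990,1
Apodemus sylvaticus,8,990,1
Apodemus sylvaticus,9,990,1
Mus musculus,2,842,0
Mus musculus,3,897,0
Mus musculus,4,950,0
Mus musculus,5,968,0
Mus musculus,6,982,0
Mus musculus,7,990,1
Mus musculus,8,990,1
Mus musculus,9,990,1
Rattus norvegicus,2,860,0
Rattus norvegicus,3,936,0
Rattus norvegicus,4,969,0
Rattus norvegicus,5,985,0
Rattus norvegicus,6,990,1
Rattus norvegicus,7,990,1
Rattus norvegicus,8,990,1
Rattus norvegicus,9,990,1
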