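specimen_id,species,family,tissue,side,d18O_co3,d18O_po4,d13C,age_class
AT01,Arvicola terrestris,arvicolid,incisor,left,28.4,15.9,,
AT01,Arvicola terrestris,arvicolid,M1,left,26.6,16.1,,
AT01,Arvicola terrestris,arvicolid,bone,,27.7,15.4,,
AT02,Arvicola terrestris,arvicolid,incisor,left,25.6,15.6,,
AT02,Arvicola terrestris,arvicolid,M1,left,26.1,15.2,,
AT02,Arvicola terrestris,arvicolid,bone,,25.5,15.7,,
AT03,Arvicola terrestris,arvicolid,incisor,left,26.4,15.4,,
AT03,Arvicola terrestris,arvicolid,M1,left,25.6,15.2,,
AT03,Arvicola terrestris,arvicolid,bone,,25.2,15.0,,
AT04,Arvicola terrestris,arvicolid,incisor,left,26.7,16.3,,
AT04,Arvicola terrestris,arvicolid,M1,left,26.6,15.3,,
AT04,Arvicola terrestris,arvicolid,bone,,24.6,13.8,,
AT05,Arvicola terrestris,arvicolid,incisor,left,25.4,13.6,,
AT05,Arvicola terrestris,arvicolid,M1,left,23.9,12.7,,
AT05,Arvicola terrestris,arvicolid,bone,,25.2,14.6,,
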