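name,intercept_a,slope_b,tissue_basis,taxa
luz_kolodny_1985,17.88,0.49,bone,Rattus
longinelli_2003,23.07,1.14,bone,Apodemus;Pitymus;Arvicola;Microtus
navarro_2004,20.98,0.572,tooth,Microtus;Myodes;Lemmus
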