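Depth,Sample,Genus,Abundance
1,HJG 01,Annulispora,5.9
1,HJG 01,Aratrisporites,7.4
1,HJG 01,Bharadwajipollenites,30.9
1,HJG 01,Cyathidites,0.7
1,HJG 01,Dictyophyllidites,13.2
1,HJG 01,Discisporites,1.5
1,HJG 01,Duplexisporites,5.9
1,HJG 01,Ginkgocycadophytus,4.4
1,HJG 01,Huabeisporites,2.9
1,HJG 01,Osmundacidites,0.7
1,HJG 01,Pteruchipollenites,25
1,HJG 01,Quadraeculina,1.5
2,HJG 02,Angiopteridaspora,11.3
2,HJG 02,Annulispora,0.7
2,HJG 02,Aratrisporites,2.4
2,HJG 02,Bharadwajipollenites,7.1
2,HJG 02,Calamospora,2
2,HJG 02,Cyathidites,4
2,HJG 02,Dictyophyllidites,7.7
2,HJG 02,Discisporites,9.1
2,HJG 02,Duplexisporites,0.7
2,HJG 02,Foveolatitriletes,5.5
2,HJG 02,Ginkgocycadophytus,7.5
2,HJG 02,Hamulatisporis,2.9
2,HJG 02,Huabeisporites,1.8
2,HJG 02,Pinuspollenites,0.7
2,HJG 02,Protohaploxypinus,1.3
2,HJG 02,Pteruchipollenites,34
2,HJG 02,Quadraeculina,1.5
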