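Genus,EPH,EPT
Angiopteridaspora,hygrophytes,megathermic
Annulispora,hygrophytes,eurythermic
Aratrisporites,hydrophytes,eurythermic
Calamospora,hygrophytes,eurythermic
Cyathidites,hygrophytes,megathermic
Dictyophyllidites,mesophytes,megathermic
Discisporites,xerophytes,megathermic
Duplexisporites,hygrophytes,megathermic
Foveolatitriletes,hygrophytes,eurythermic
Ginkgocycadophytus,mesophytes,mesothermic
Hamulatisporis,hygrophytes,eurythermic
Huabeisporites,hygrophytes,megathermic
Osmundacidites,hygrophytes,eurythermic
Pinuspollenites,mesophytes,microthermic
Protohaploxypinus,xerophytes,megathermic
Pteruchipollenites,mesophytes,megathermic
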