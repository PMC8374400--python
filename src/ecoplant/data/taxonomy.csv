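Kingdom,Phylum,Class,Order,Family,Genus
Plantae,Gymnospermae,,Bennettitales,Williamsoniaceae,Bharadwajipollenites
Plantae,Gymnospermae,,Bennettitales,Cycadeoidaceae,Huabeisporites
Plantae,Gymnospermae,,Corystospermales,Umkomasiaceae,Pteruchipollenites
Plantae,Pteridophytes,Polypodiopsida,Cyatheales,Cyatheaceae,Cyathidites
Plantae,Pteridophytes,Polypodiopsida,Cyatheales,Cibotiaceae,Duplexisporites
Plantae,Pteridophytes,Equisetopsida,Equisetales,Equisetaceae,Calamospora
Plantae,Gymnospermae,,Ginkgoales,Ginkgoaceae,Ginkgocycadophytus
Plantae,Pteridophytes,Polypodiopsida,Gleicheniales,Dipteridaceae,Dictyophyllidites
Plantae,Pteridophytes,Lycopodiopsida,Isoetales,Pleuromeiaceae,Aratrisporites
Plantae,Pteridophytes,Lycopodiopsida,Lycopodiales,Lycopodiaceae,Hamulatisporis
Plantae,Pteridophytes,Lycopodiopsida,Lycopodiales,Lycopodiaceae,Foveolatitriletes
Plantae,Pteridophytes,Marattiopsida,Marattiales,Marattiaceae,Angiopteridaspora
Plantae,Bryophytes,Anthocerotopsida,Notothyladales,Notothyladaceae,Annulispora
Plantae,Pteridophytes,Polypodiopsida,Osmundales,Osmundaceae,Osmundacidites
Plantae,Gymnospermae,,Peltaspermales,Peltaspermaceae,Protohaploxypinus
Plantae,Gymnospermae,,Pinales,Pinaceae,Pinuspollenites
Plantae,Gymnospermae,,Pinales,Cheirolepidiaceae,Discisporites
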