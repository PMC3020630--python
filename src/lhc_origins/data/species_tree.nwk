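(Gloeobacter,((Synechocystis,Nostoc)CyanoCore,((Cyanophora,Glaucocystis)Glaucophyta,(((Cyanidioschyzon,Galdieria)RedAlgae,(Phaeodactylum,Thalassiosira)Diatoms)RedLineage,((Chlamydomonas,Ostreococcus)Chlorophyta,(Physcomitrella,(Pinus,(Oryza,Arabidopsis)Angiosperms)SeedPlants)Streptophyta)GreenLineage)RedGreen)Plantae)Crown)Root;
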