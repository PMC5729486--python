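order,species,N,K,D,C,L,H,P
Afrosoricida,Chrysospalax trevelyani,112,328,0.053,0.456,2.810,1.448,0.820
Afrosoricida,Micropotamogale ruwenzorii,108,329,0.057,0.482,2.771,1.449,0.784
Carnivora,Canis lupus,123,368,0.049,0.351,2.714,1.529,0.784
Carnivora,Civettictis civetta,113,357,0.056,0.468,2.706,1.504,0.767
Carnivora,Felis silvestris,103,320,0.061,0.452,2.650,1.401,0.784
Carnivora,Galictis cuja,118,322,0.047,0.448,2.928,1.416,0.780
Carnivora,Zalophus californianus,118,338,0.049,0.479,2.795,1.430,0.801
Cetartiodactyla,Babyrousa babyrussa,106,344,0.062,0.398,2.734,1.409,0.784
Cetartiodactyla,Bos taurus,108,329,0.057,0.410,2.777,1.395,0.789
Cetartiodactyla,Camelus bactrianus,96,232,0.051,0.295,2.903,1.268,0.771
Cetartiodactyla,Giraffa camelopardalis,106,309,0.056,0.435,2.731,1.421,0.793
Cetartiodactyla,Kogia breviceps,96,219,0.048,0.488,3.099,1.316,0.825
Chiroptera,Pteropus vampyrus,92,260,0.062,0.452,2.778,1.329,0.732
Chiroptera,Vespertilio murinus,96,264,0.058,0.476,2.821,1.358,0.729
Cingulata,Dasypus novemcinctus,95,279,0.062,0.524,2.769,1.331,0.844
Dasyuromorpha,Sarcophilus harrisii,118,390,0.056,0.449,2.714,1.502,0.779
Didelphimorphia,Didelphis virginiana,108,374,0.065,0.385,2.668,1.413,0.795
Diprotodontia,Macropus rufus,112,355,0.057,0.446,2.726,1.425,0.725
Diprotodontia,Phascolarctos cinereus,119,397,0.057,0.429,2.699,1.538,0.710
Diprotodontia,Trichosurus vulpecula,109,348,0.059,0.402,2.743,1.432,0.725
Eulipotyphla,Erinaceus europaeus,104,330,0.062,0.441,2.747,1.419,0.734
Eulipotyphla,Scalopus aquaticus,108,322,0.056,0.425,2.788,1.439,0.728
Eulipotyphla,Suncus murinus,104,304,0.057,0.411,2.835,1.418,0.753
Hyracoidea,Procavia capensis,115,340,0.052,0.451,2.840,1.507,0.815
Lagomorpha,Oryctolagus cuniculus,122,343,0.046,0.422,2.831,1.556,0.786
Monotremata,Ornithorhynchus anatinus,84,282,0.081,0.382,2.575,1.179,0.765
Monotremata,Tachyglossus aculeatus,85,260,0.073,0.389,2.709,1.183,0.791
Notoryctemorphia,Notoryctes typhlops,112,363,0.058,0.455,2.736,1.485,0.806
Paucituberculata,Caenolestes fuliginosus,122,383,0.052,0.435,2.767,1.544,0.770
Peramelemorphia,Macrotis lagotis,120,396,0.055,0.434,2.720,1.541,0.790
Perissodactyla,Equus caballus,124,327,0.043,0.454,2.874,1.555,0.774
Perissodactyla,Tapirus indicus,114,321,0.050,0.463,2.862,1.463,0.815
Pholidota,Manis pentadactyla,101,292,0.058,0.456,2.873,1.375,0.791
Pilosa,Bradypus tridactylus,110,318,0.053,0.548,2.909,1.293,0.782
Pilosa,Choloepus didactylus,90,255,0.064,0.489,2.708,1.339,0.762
Pilosa,Cyclopes didactylus,96,260,0.057,0.456,2.917,1.319,0.820
Primates,Homo sapiens,113,334,0.053,0.512,2.712,1.442,0.793
Primates,Loris tardigradus,114,344,0.053,0.352,2.731,1.470,0.808
Primates,Macaca mulatta,122,369,0.050,0.344,2.719,1.504,0.812
Proboscidea,Elephas maximus,110,273,0.046,0.439,2.829,1.424,0.797
Rodentia,Chinchilla lanigera,108,320,0.055,0.404,2.761,1.423,0.831
Rodentia,Heteromys desmarestianus,96,294,0.064,0.356,2.719,1.256,0.803
Rodentia,Neotoma fuscipes,120,333,0.047,0.409,2.825,1.521,0.814
Rodentia,Pedetes capensis,112,323,0.052,0.434,2.775,1.474,0.802
Rodentia,Sciurus vulgaris,130,364,0.043,0.421,2.807,1.575,0.780
Scandentia,Ptilocercus lowii,114,336,0.052,0.483,2.785,1.490,0.719
Sirenia,Dugong dugon,106,310,0.056,0.505,2.782,1.413,0.795
Tubulidentata,Orycteropus afer,101,272,0.054,0.504,2.860,1.308,0.783
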