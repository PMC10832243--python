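compound	degree
Luteolin	48
Baicalein	34
Kaempferol	31
Wogonin	21
Hesperetin	15
Isorhamnetin	14
Hispidulin	12
Chrysoeriol	11
Diosmetin	10
Calycosin	10
7-O-Methylluteolin	10
Kumatakenin	9
Odoratin	9
Pratensein	8
Liquiritigenin	7
Mosloflavone	6
Formononetin	6
3'-O-Methylorobol	6
Medicarpin	4
Marmesin	3
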