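run,pos27,pos28,pos29,pos31,pos99,pos100,energy_kcal_mol
1,Trp,Trp,Trp,Trp,Trp,Trp,-750
2,Trp,Phe,Phe,Phe,Phe,Phe,-717
3,Trp,His,His,His,His,His,-677
4,Trp,Asp,Asp,Asp,Asp,Asp,-650
5,Trp,Tyr,Tyr,Tyr,Tyr,Tyr,-735
6,Phe,Trp,Phe,His,Asp,Tyr,-705
7,Phe,Phe,His,Asp,Tyr,Trp,-677
8,Phe,His,Asp,Tyr,Trp,Phe,-692
9,Phe,Asp,Tyr,Trp,Phe,His,-791
10,Phe,Tyr,Trp,Phe,His,Asp,-683
11,His,Trp,His,Tyr,Phe,Asp,-672
12,His,Phe,Asp,Trp,His,Tyr,-701
13,His,His,Tyr,Phe,Asp,Trp,-737
14,His,Asp,Trp,His,Tyr,Phe,-673
15,His,Tyr,Phe,Asp,Trp,His,-689
16,Asp,Trp,Asp,Phe,Tyr,His,-735
17,Asp,Phe,Tyr,His,Trp,Asp,-656
18,Asp,His,Trp,Asp,Phe,Tyr,-673
19,Asp,Asp,Phe,Tyr,His,Trp,-686
20,Asp,Tyr,His,Trp,Asp,Phe,-701
21,Tyr,Trp,Tyr,Asp,His,Phe,-686
22,Tyr,Phe,Trp,Tyr,Asp,His,-741
23,Tyr,His,Phe,Trp,Tyr,Asp,-675
24,Tyr,Asp,His,Phe,Trp,Tyr,-675
25,Tyr,Tyr,Asp,His,Phe,Trp,-740
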