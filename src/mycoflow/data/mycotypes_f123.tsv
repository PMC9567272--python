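genus	domain	mycotype
Malassezia	fungus	F1
Ramularia	fungus	F1
Trichosporon	fungus	F1
Candida	fungus	F2
Aspergillus	fungus	F2
Tilletiopsis	fungus	F3
Penicillium	fungus	F3
Cryptococcus	fungus	F3
Puccinia	fungus	F3
Agaricus	fungus	F3
Alternaria	fungus	F3
Phialocephala	fungus	F3
Fusarium	fungus	F3
Hyphopichia	fungus	F3
Exophiala	fungus	F3
Stereum	fungus	F3
Colletotrichum	fungus	F3
Dissoconium	fungus	F3
Aureobasidium	fungus	F3
Talaromyces	fungus	F3
Cutaneotrichosporon	fungus	F3
Yarrowia	fungus	F3
Trichoderma	fungus	F3
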