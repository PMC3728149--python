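species	population	host	study
T_bartmani	JL	Abies_concolor	interspecific
T_bartmani	RS	Abies_concolor	interspecific
T_boharti	ML	Adenostoma	interspecific
T_californicum	Fremont	Adenostoma	interspecific
T_californicum	HW1	Quercus	interspecific
T_chumash	HW2	Adenostoma	interspecific
T_chumash	ED	Ceanothus	interspecific
T_cristinae	WTA	Adenostoma	interspecific
T_cristinae	OJ	Ceanothus	interspecific
T_knulli	Trail	Sequoia	interspecific
T_knulli	BC	Ceanothus	interspecific
T_petita	Ma	Ceanothus	interspecific
T_petita	Mo	Ceanothus	interspecific
T_podura	HW243	Adenostoma	interspecific
T_podura	Seq	Ceanothus	interspecific
T_poppensis	Fish	Pseudotsuga	interspecific
T_poppensis	Mado	Sequoia	interspecific
T_cristinae	OGA	Adenostoma	intraspecific
T_cristinae	R23A	Adenostoma	intraspecific
T_cristinae	SC	Ceanothus	intraspecific
T_cristinae	PEC	Ceanothus	intraspecific
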