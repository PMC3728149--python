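female_species	T_bartmani	T_boharti	T_californicum	T_chumash	T_cristinae	T_knulli	T_petita	T_podura	T_poppensis
T_bartmani	30	4	9	12	25	3	3	13	25
T_boharti	8	4	35	13	13	4	8	20	13
T_californicum	11	4	22	11	27	13	9	30	41
T_chumash	10	3	16	19	19	19	20	34	26
T_cristinae	10	4	28	15	106	12	10	26	30
T_knulli	9	3	7	12	20	17	16	22	18
T_petita	11	2	19	6	28	21	8	20	21
T_podura	24	12	3	24	31	4	18	20	15
T_poppensis	10	11	28	10	24	24	8	26	53
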