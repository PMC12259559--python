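sample_id	gender	age	diagnosis	outcome
P01	Male	70	SEPSIS	Partial recovery+ discharged
P02	Female	69	SEPSIS + liver abscess	Recovery
P03	Male	78	SEPTIC SHOCK +MODS	Improvement
P04	Female	42	SEPTIC SHOCK + staphylococcus	Partial recovery+ discharged
P05	Male	76	SEPSIS + gastric track infection	Recovery
P06	Male	52	SEPSIS + gastric track infection	Recovery
P07	Male	97	SEPTIC SHOCK + MODS	Death
P08	Female	58	SEPTIC SHOCK + urinary tract infection	Recovery
P09	Female	58	SEPSIS + acute pancreatitis + MODS + pneumonia + ARDS	Improvement
P10	Female	71	SEPSIS	Recovery
P11	Female	59	SEPTIC SHOCK	Improvement
P12	Female	57	SEPSIS	Improvement
P13	Female	57	SEPSIS	Refused further treatment+ discharged
P14	Female	89	SEPSIS + gastrointestinal perforation + intra-abdominal infections + pneumonia	Recovery
P15	Male	43	SEPSIS + gallbladder perforation	Recovery
P16	Female	70	SEPTIC SHOCK + urinary tract infection	Improvement
P17	Male	43	SEPSIS	Improvement
P18	Female	56	SEPTIC SHOCK	Recovery
P19	Male	78	Severe pneumonia + COVID	Refused further treatment+ discharged
P20	Male	78	SEPSIS + acute liver failure	Improvement
P21	Female	83	SEPTIC SHOCK	Recovery
P22	Male	85	SEPSIS + gastric bleeding	Death
P23	Male	74	SEPSIS + severe pneumonia	Improvement
P24	Female	60	SEPSIS + anemia	Improvement
P25	Female	74	SEPSIS + severe pneumonia	Improvement
P26	Female	77	Severe fever with thrombocytopenia syndrome bunyavirus	Refused further treatment+ discharged
P27	Male	21	SEPTIC SHOCK	Improvement
P28	Female	49	SEPTIC SHOCK	Improvement
P29	Male	74	SEPSIS + severe pneumonia	Improvement
P30	Female	82	SEPSIS + acute pulmonary edema	Improvement
P31	Female	73	SEPTIC SHOCK	Improvement
P32	Female	68	SEPSIS +MODS	Death
C01	Female	52	Healthy control	N/A
C02	Male	59	Healthy control	N/A
C03	Male	56	Healthy control	N/A
C04	Male	55	Healthy control	N/A
C05	Female	58	Healthy control	N/A
C06	Female	55	Healthy control	N/A
C07	Female	61	Healthy control	N/A
C08	Male	54	Healthy control	N/A
C09	Female	58	Healthy control	N/A
C10	Female	55	Healthy control	N/A
C11	Female	55	Healthy control	N/A
C12	Female	50	Healthy control	N/A
C13	Female	50	Healthy control	N/A
C14	Male	56	Healthy control	N/A
C15	Male	60	Healthy control	N/A
C16	Male	59	Healthy control	N/A
C17	Male	54	Healthy control	N/A
C18	Female	65	Healthy control	N/A
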