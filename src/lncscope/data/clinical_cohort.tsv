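sample_id	group	age	sex	invasiveness	laterality
RB1	tumor	6 Y	Male	Invasive	OD
RB2	tumor	3 Y	Male	Non-Invasive	OS
RB3	tumor	2 Y	Female	Non-Invasive	OD
RB4	tumor	3 Y	Female	Non-Invasive	OD
RB5	tumor	1 Y	Female	Invasive	OD
RB6	tumor	3 Y	Male	Non-Invasive	OS
RB7	tumor	8 Months	Male	Invasive	OD
C1	control	12 Y	N/A	N/A	N/A
C2	control	5 Y	N/A	N/A	N/A
C3	control	22 Y	N/A	N/A	N/A
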