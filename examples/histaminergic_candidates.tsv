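drug_name	similarity	p_value	gsea_score	drug_id	target
Amodiaquine	1	0.00806	3	DB00613	HNMT
Rupatadine	0.62791	0.01412	3	DB11614	H1 receptor
Diphenhydramine	0.62791	0.01571	2	DB01075	H1 receptor
Dimetindene	0.62791	0.01654	na	DB08801	H1 receptor
Butriptyline	0.50388	0.02857	na	DB09016	H1 receptor
Clomipramine	0.37984	0.03232	3	DB01242	H1 receptor
Epinastine	0.37984	0.0044	2	DB00751	H1 receptor
Cyproheptadine	0.36213	0.01584	3	DB00434	H1 receptor
Trazodone	0.36213	0.03221	3	DB00656	H1 receptor
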