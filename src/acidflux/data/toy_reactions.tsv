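reaction_id	equation	lower_bound	upper_bound	tag	acid
T_GLC	glc_e --> 6 cc	0.0	1000.0	GLUCOSE_EX	
T_XYL	xyl_e --> 5 cc	0.0	1000.0	XYLOSE_EX	
T_PIE	pi_e --> pi_c	0.0	1000.0	EXTERNAL_P_IN	
PI	polyp <=> pi_c	-1000.0	1000.0	STORED_P_IN	
GOX_E	glc_e --> glcn_s	0.0	0.0	GOX	
BIOMASS	249.561 cc + 0.171434 pi_c --> 213 co2_e	0.0	1000.0	BIOMASS	
SYN_CIT	6 cc --> cit_c	0.0	1000.0	OTHER	
SYN_OXA	2 cc --> oxa_c	0.0	1000.0	OAH	
SEC_BUDGET	--> sec_cap	0.0	0.12	OTHER	
HPE	h_e -->	0.0	1000.0	PROTON_OUT	
SEC_CIT	cit_c + sec_cap --> cit_s	0.0	1000.0	ACID_SECRETION	citric
DISS_CIT	cit_s --> cit_e + 0.0695434 h_e	0.0	1000.0	ACID_DISSOCIATION	citric
SEC_OXA	oxa_c + sec_cap --> oxa_s	0.0	1000.0	ACID_SECRETION	oxalic
DISS_OXA	oxa_s --> oxa_e + 0.8537 h_e	0.0	1000.0	ACID_DISSOCIATION	oxalic
SEC_GLCN	glcn_c --> glcn_s	0.0	1000.0	ACID_SECRETION	gluconic
DISS_GLCN	glcn_s --> glcn_e + 0.0195623 h_e	0.0	1000.0	ACID_DISSOCIATION	gluconic
SEC_ACE	ace_c --> ace_s	0.0	1000.0	ACID_SECRETION	acetic
DISS_ACE	ace_s --> ace_e + 0.00174679 h_e	0.0	1000.0	ACID_DISSOCIATION	acetic
SEC_MAL	mal_c --> mal_s	0.0	1000.0	ACID_SECRETION	malic
DISS_MAL	mal_s --> mal_e + 0.0336392 h_e	0.0	1000.0	ACID_DISSOCIATION	malic
SEC_SUC	suc_c --> suc_s	0.0	1000.0	ACID_SECRETION	succinic
DISS_SUC	suc_s --> suc_e + 0.00617322 h_e	0.0	1000.0	ACID_DISSOCIATION	succinic
SEC_LAC	lac_c --> lac_s	0.0	1000.0	ACID_SECRETION	lactic
DISS_LAC	lac_s --> lac_e + 0.0136159 h_e	0.0	1000.0	ACID_DISSOCIATION	lactic
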