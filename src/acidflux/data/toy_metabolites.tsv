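metabolite_id	name	compartment	carbon_count	phosphorus_count	boundary
glc_e	glucose (external)	external	6	0	1
xyl_e	xylose (external)	external	5	0	1
pi_e	phosphate (external)	external	0	1	1
polyp	stored phosphate pool	cytosol	0	1	1
co2_e	carbon dioxide (external)	external	1	0	1
cc	carbon currency (C1)	cytosol	1	0	0
pi_c	phosphate (cytosol)	cytosol	0	1	0
h_e	proton (external)	external	0	0	0
sec_cap	acid secretion capacity	cytosol	0	0	0
cit_c	citric acid (cytosol)	cytosol	6	0	0
cit_s	citric acid (secreted, undissociated)	external	6	0	0
cit_e	citric acid (external pool)	external	6	0	1
oxa_c	oxalic acid (cytosol)	cytosol	2	0	0
oxa_s	oxalic acid (secreted, undissociated)	external	2	0	0
oxa_e	oxalic acid (external pool)	external	2	0	1
glcn_c	gluconic acid (cytosol)	cytosol	6	0	0
glcn_s	gluconic acid (secreted, undissociated)	external	6	0	0
glcn_e	gluconic acid (external pool)	external	6	0	1
ace_c	acetic acid (cytosol)	cytosol	2	0	0
ace_s	acetic acid (secreted, undissociated)	external	2	0	0
ace_e	acetic acid (external pool)	external	2	0	1
mal_c	malic acid (cytosol)	cytosol	4	0	0
mal_s	malic acid (secreted, undissociated)	external	4	0	0
mal_e	malic acid (external pool)	external	4	0	1
suc_c	succinic acid (cytosol)	cytosol	4	0	0
suc_s	succinic acid (secreted, undissociated)	external	4	0	0
suc_e	succinic acid (external pool)	external	4	0	1
lac_c	lactic acid (cytosol)	cytosol	3	0	0
lac_s	lactic acid (secreted, undissociated)	external	3	0	0
lac_e	lactic acid (external pool)	external	3	0	1
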