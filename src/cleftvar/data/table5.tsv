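section	category	n	percent
gender	males	36	62.07
gender	females	22	37.93
cleft_type	ns_clp	48	82.76
cleft_type	ns_clp_unilateral_right	10	17.24
cleft_type	ns_clp_unilateral_left	21	36.21
cleft_type	ns_clp_bilateral	15	25.86
cleft_type	ns_clp_side_unknown	2	3.45
cleft_type	ns_cl	10	17.24
cleft_type	ns_cl_unilateral_right	3	5.17
cleft_type	ns_cl_unilateral_left	2	3.45
cleft_type	ns_cl_bilateral	1	1.72
cleft_type	ns_cl_side_unknown	4	6.9
anomalies	associated_anomalies	16	27.59
anomalies	kidney_defects	2	3.45
family_history	positive_family_history	19	32.76
family_history	immediate_family	6	10.34
family_history	extended_family	13	22.41
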