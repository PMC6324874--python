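# Reference WS mutation spectrum for P. fluorescens SBW25, transcribed from the
# published main-text counts of the WS forecasting study: 105 no-selection mutants
# (wsp 46, aws 41, mws 18), the awsX dY77-Q87 hotspot (20), awsR T27P (9), the
# awsX dP34-A46 deletion (2), eight further Aws substitutions observed once,
# wspA as the most-mutated gene without selection (15/46), Wsp multiplicities
# (six sites twice, one three times, one five times), and 15/24 Wsp mutants under
# selection with no wspA hits. Entries whose mutation_id starts with "syn_" are
# SYNTHETIC fillers for counts the source tables do not itemize; gene-level splits
# not printed in the main text are likewise synthetic.
pathway	gene	mutation_id	count	condition
Aws	awsX	dY77-Q87	20	no_selection
Aws	awsX	dP34-A46	2	no_selection
Aws	awsR	T27P	9	no_selection
Aws	awsR	sub1	1	no_selection
Aws	awsR	sub2	1	no_selection
Aws	awsR	sub3	1	no_selection
Aws	awsR	sub4	1	no_selection
Aws	awsX	sub5	1	no_selection
Aws	awsX	sub6	1	no_selection
Aws	awsO	sub7	1	no_selection
Aws	awsO	sub8	1	no_selection
Aws	awsX	syn_aws1	1	no_selection
Aws	awsR	syn_aws2	1	no_selection
Wsp	wspA	syn_wspA_rep1	2	no_selection
Wsp	wspA	syn_wspA_rep2	2	no_selection
Wsp	wspA	syn_wspA_s1	1	no_selection
Wsp	wspA	syn_wspA_s2	1	no_selection
Wsp	wspA	syn_wspA_s3	1	no_selection
Wsp	wspA	syn_wspA_s4	1	no_selection
Wsp	wspA	syn_wspA_s5	1	no_selection
Wsp	wspA	syn_wspA_s6	1	no_selection
Wsp	wspA	syn_wspA_s7	1	no_selection
Wsp	wspA	syn_wspA_s8	1	no_selection
Wsp	wspA	syn_wspA_s9	1	no_selection
Wsp	wspA	syn_wspA_s10	1	no_selection
Wsp	wspA	syn_wspA_s11	1	no_selection
Wsp	wspF	syn_wspF_rep5	5	no_selection
Wsp	wspF	syn_wspF_rep1	2	no_selection
Wsp	wspF	syn_wspF_rep2	2	no_selection
Wsp	wspF	syn_wspF_s1	1	no_selection
Wsp	wspF	syn_wspF_s2	1	no_selection
Wsp	wspF	syn_wspF_s3	1	no_selection
Wsp	wspF	syn_wspF_s4	1	no_selection
Wsp	wspF	syn_wspF_s5	1	no_selection
Wsp	wspE	syn_wspE_rep3	3	no_selection
Wsp	wspE	syn_wspE_rep1	2	no_selection
Wsp	wspE	syn_wspE_rep2	2	no_selection
Wsp	wspE	syn_wspE_s1	1	no_selection
Wsp	wspE	syn_wspE_s2	1	no_selection
Wsp	wspE	syn_wspE_s3	1	no_selection
Wsp	wspE	syn_wspE_s4	1	no_selection
Wsp	wspE	syn_wspE_s5	1	no_selection
Wsp	wspC	syn_wspC_s1	1	no_selection
Wsp	wspC	syn_wspC_s2	1	no_selection
Wsp	wspR	syn_wspR_s1	1	no_selection
Wsp	wspR	syn_wspR_s2	1	no_selection
Wsp	wspR	syn_wspR_s3	1	no_selection
Mws	mwsR	syn_mwsR_rep1	2	no_selection
Mws	mwsR	syn_mwsR_rep2	2	no_selection
Mws	mwsR	syn_mwsR_s1	1	no_selection
Mws	mwsR	syn_mwsR_s2	1	no_selection
Mws	mwsR	syn_mwsR_s3	1	no_selection
Mws	mwsR	syn_mwsR_s4	1	no_selection
Mws	mwsR	syn_mwsR_s5	1	no_selection
Mws	mwsR	syn_mwsR_s6	1	no_selection
Mws	mwsR	syn_mwsR_s7	1	no_selection
Mws	mwsR	syn_mwsR_s8	1	no_selection
Mws	mwsR	syn_mwsR_s9	1	no_selection
Mws	mwsR	syn_mwsR_s10	1	no_selection
Mws	mwsR	syn_mwsR_s11	1	no_selection
Mws	mwsR	syn_mwsR_s12	1	no_selection
Mws	mwsR	syn_mwsR_s13	1	no_selection
Mws	mwsR	syn_mwsR_s14	1	no_selection
Wsp	wspF	syn_sel_wspF	9	selection
Wsp	wspE	syn_sel_wspE	5	selection
Wsp	wspC	syn_sel_wspC	1	selection
Aws	awsX	syn_sel_awsX	5	selection
Aws	awsR	syn_sel_awsR	3	selection
Mws	mwsR	syn_sel_mwsR	1	selection
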