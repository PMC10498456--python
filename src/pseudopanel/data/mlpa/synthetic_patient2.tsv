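probe_id	target	ratio
TNXB_ex35_p1	exon35	0.0
TNXB_ex35_p2	exon35	0.02
CYP21A2_p1	marker_c	1.0
CYP21A2_p2	marker_c	0.98
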