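family_id	allele_1	allele_2
P1	cnv_deletion(exons 2-3)	cnv_deletion(exons 2-3)
P2	conversion_type1	conversion_type1
P3	point_variant(c.1650_1651del)	point_variant(c.1650_1651del)
P4	point_variant(c.10274C>G)	fusion_type1
P5	point_variant(c.6948del)	fusion_type1
P6	conversion_type2	conversion_type2
P7	conversion_type1	fusion_type2
P8	point_variant(c.8585G>A)	conversion_type1
P9	point_variant(c.9271dup)	fusion_type1
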