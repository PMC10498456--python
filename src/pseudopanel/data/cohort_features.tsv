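patient_id	sex	age	deceased	ethnicity	skin_hyperextensibility	velvety_skin_texture	atrophic_scarring	generalized_joint_hypermobility	recurrent_dislocations	easily_bruisable_skin	eye_bleeding	hand_deformities	foot_deformities	muscle_weakness	muscle_atrophy	gastrointestinal	hematoma
P1	Female	60	no	Japanese	+	+	+	+	+	+	na	+|acrogeric hands, mallet fingers, clinodactyly, brachydactyly	+|broad/plump forefoot, brachydactyly with excessive skin, pes planus, hallux valgus, piezogenic papules	+	+	+|reflux esophagitis, multiple gastric polyps, low-grade tubular adenoma	na
P2	Male	65	no	Japanese	-	-	-	-|only fingers and elbows	-	+	+|subconjunctiva	+|acrogeric hands, brachydactyly	+|broad/plump forefoot, pes planus	na	na	+|recurrent intestinal obstruction, colonic diverticulitis, rectal prolapse, gallstones, constipation	na
P3	Male	62	yes	Japanese	na	na	na	na	na	na	na	na	na	na	na	+|intestinal obstruction	na
P4	Female	27	no	Japanese	+	+	na	+	+|shoulder	+	na	-	-	-	-	na	na
P5	Female	47	no	Japanese	+	-	+	+	+	+	+|conjunctiva	+|acrogeric hands	+|pes planus, hallux valgus	+	+	+|small bowel diverticula and perforation, constipation, vomiting and diarrhea after eating	na
P6	Female	59	no	Chinese	+	na	+	+	+|shoulder, finger, hip, toe	+	na	na	na	na	na	+|anal prolapse, anal laceration, gallstones, appendicitis	+|subcutaneous, rectal
P7	Male	61	no	Japanese	+	+	-	-|only elbows and knees	+|shoulder	+	na	na	+|pes planus	na	na	+|small bowel perforation, esophageal perforation, diverticulitis	na
P8	Female	8	no	Japanese	+	+	-	+	+|finger	+	+|sclera	+|mallet fingers, brachydactyly	+|broad/plump forefoot, pes planus, piezogenic papules	-	-	+|anal prolapse	na
P9	Female	69	no	Japanese	+	-	+	-	+|shoulder, toe	+	na	+|acrogeric hands, clinodactyly, brachydactyly	+|broad/plump forefoot, brachydactyly with excessive skin, pes planus	+	-	+|small bowel perforation, rectal prolapse, gallstones	+|subcutaneous
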