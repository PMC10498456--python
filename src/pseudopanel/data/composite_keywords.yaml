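# Keyword rules for composite gastrointestinal categories.  The source table
# stores these as prose; which entries count toward each category is an
# editorial choice, so the mapping is shipped as data and is user-editable.
# "diverticul" deliberately matches both diverticula and diverticulitis.
perforation:
  - perforation
diverticulitis:
  - diverticul
# "rectal" counts as gastrointestinal bleeding only in the hematoma column,
# so it does not collide with "rectal prolapse" in the GI column
gastrointestinal_bleeding:
  columns: [hematoma]
  keywords:
    - gastrointestinal bleeding
    - rectal
intestinal_obstruction:
  - obstruction
rectal_anal_prolapse:
  - rectal prolapse
  - anal prolapse
gallstones:
  - gallstones
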