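key	full_forms
heent	head|eye|ear|nose|throat
ext	extremity
ue	upper extremity
le	lower extremity
ruq	abdomen
luq	abdomen
rlq	abdomen
llq	abdomen
gi	abdomen
cns	brain
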