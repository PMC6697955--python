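surface	canonical
left	left
right	right
bilateral	bilateral
bilaterally	bilateral
upper	upper
lower	lower
proximal	proximal
proximally	proximal
distal	distal
distally	distal
anterior	anterior
anteriorly	anterior
posterior	posterior
posteriorly	posterior
medial	medial
medially	medial
lateral	lateral
laterally	lateral
superior	superior
inferior	inferior
dorsal	dorsal
ventral	ventral
cranial	cranial
caudal	caudal
superficial	superficial
deep	deep
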