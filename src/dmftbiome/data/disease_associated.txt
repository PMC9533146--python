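# Default curated list: genera commonly associated with oral disease
# (caries / periodontal disease literature). Editable.
Porphyromonas
Tannerella
Treponema
Fusobacterium
Prevotella
Lactobacillus
Scardovia
Parvimonas
Filifactor
Selenomonas
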