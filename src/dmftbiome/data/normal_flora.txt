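# Default curated list: genera commonly reported as normal oral flora.
# Editable; results should always be reported with the list version used.
Streptococcus
Staphylococcus
Corynebacterium
Veillonella
Granulicatella
Gemella
Neisseria
Haemophilus
Rothia
Abiotrophia
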