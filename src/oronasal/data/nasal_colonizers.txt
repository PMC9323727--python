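# Genera reported to colonize the nasal cavity at high rates; edit to taste.
Pseudomonas
Dolosigranulum
Moraxella
Serratia
Staphylococcus
Corynebacterium
Stenotrophomonas
Achromobacter
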