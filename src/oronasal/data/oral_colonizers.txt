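# Genera reported to colonize the oral cavity at high rates; edit to taste.
Streptococcus
Gemella
Veillonella
Prevotella
Alloprevotella
Neisseria
Rothia
Actinomyces
Haemophilus
Granulicatella
Atopobium
Porphyromonas
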