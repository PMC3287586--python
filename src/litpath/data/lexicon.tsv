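# Default biointeraction word lexicon: word<TAB>polarity
# polarity in {activation, repression, neutral}; morphological variants are
# listed explicitly (no stemming).
activates	activation
activate	activation
activated	activation
induces	activation
induce	activation
induced	activation
stimulates	activation
stimulate	activation
stimulated	activation
upregulates	activation
upregulate	activation
upregulated	activation
up-regulates	activation
promotes	activation
promote	activation
promoted	activation
enhances	activation
enhance	activation
enhanced	activation
transactivates	activation
triggers	activation
maintains	activation
represses	repression
repress	repression
repressed	repression
inhibits	repression
inhibit	repression
inhibited	repression
downregulates	repression
downregulate	repression
downregulated	repression
down-regulates	repression
suppresses	repression
suppress	repression
suppressed	repression
silences	repression
silenced	repression
antagonizes	repression
abolishes	repression
blocks	repression
prevents	repression
binds	neutral
bind	neutral
bound	neutral
associates	neutral
interacts	neutral
interact	neutral
phosphorylates	neutral
phosphorylate	neutral
phosphorylated	neutral
dephosphorylates	neutral
regulates	neutral
regulate	neutral
regulated	neutral
modulates	neutral
modulate	neutral
targets	neutral
controls	neutral
mediates	neutral
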