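# Marker-term scorer configuration for the five symptomatic outcomes.
# Each outcome maps to the terms whose presence in a post flags it
# positive. The synthetic generator emits the first marker of each list
# when it materializes a symptomatic post, so scorer and generator agree
# by construction; replace these lists (or plug in a real classifier)
# for natural-language corpora.
depression: [downhearted, hopelessmood]
anxiety: [onedge, racingworry]
stress: [overloadedmind, burntout]
suicidal_ideation: [enditthoughts]
psychosis: [unrealvoices]
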