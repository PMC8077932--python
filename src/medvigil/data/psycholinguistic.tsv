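# Small open psycholinguistic lexicon fixture: category -> word list
# (pipe-separated). Categories are disjoint so per-category relative
# frequencies sum to at most 1. Swap in a richer lexicon via the same
# TSV schema for real analyses.
category	words
positive_affect	happy|glad|great|love|excited|good|nice|awesome|hope|fun
negative_affect	sad|angry|hate|terrible|awful|cry|hurt|upset|miserable|fear
social	friend|family|talk|people|party|together|visit|call|meet|share
cognition	think|know|because|reason|wonder|understand|believe|maybe|question|idea
body	tired|sleep|eat|head|stomach|body|sick|ache|dizzy|nausea
first_person	i|me|my|mine|myself
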