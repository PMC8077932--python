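# Seed terms for the five clinically significant antidepressant
# side-effect domains. Each category lists the anchor terms whose
# in-post co-occurrence defines the normalized prevalence tables.
sleep: [sleep, asleep, insomnia, awake]
weight: [weight]
eating: [eat, eating, hungry, appetite]
pain: [pain, ache]
sexual: [sex, sexual, asexual, libido]
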