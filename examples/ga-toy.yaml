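# Desk-scale toy recovery configuration
population: 50
generations: 100
model: toy
seed: 0
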