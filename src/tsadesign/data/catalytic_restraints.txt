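# Flat-bottom catalytic-contact restraints for the GUS / pNP-GLU active site.
# chainA resA atomA chainB resB atomB d_min d_max k_min k_max
# Distances in Å; force constants in kJ/(mol·Å²); k_min walls the short side.
A 413 HE2 L 1 O6 1.7 1.8 75.0 100.0
A 504 OE2 L 1 C1 2.5 2.6 75.0 100.0
A 467 HH12 L 1 O7 1.7 1.8 75.0 100.0
A 467 HH22 L 1 O8 1.7 1.8 75.0 100.0
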