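probe_id	direction
G3P00	G3up
G3P01	G3up
G3P02	G3up
G3P03	G3up
G3P04	G3up
G3P05	G3up
G3P06	G3up
G3P07	G3up
G1P00	G1up
G1P01	G1up
G1P02	G1up
G1P03	G1up
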