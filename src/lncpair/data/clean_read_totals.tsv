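group	clean_reads	read_length_bp
D/E-0.61	278269246	150
D/E-1.46	269325362	150
D/E-2.75	279307386	150
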