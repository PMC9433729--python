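kind	temperature	n
snv	hot	24
snv	warm	6
snv	tepid	15
snv	cool	5
snv	cold	4
cnv	.	10
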