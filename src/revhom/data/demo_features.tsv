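name	category	pattern
pka_site	motif	RR.S
sh3_ligand	motif	P..P
nls_classical	motif	K[KR].[KR]
polyq_repeat	repeat	Q{4,}
rg_repeat	repeat	(?:RG){2,}
sr_repeat	repeat	(?:SR){2,}
acidic_tract	physicochemical	[DE]{3,}
basic_tract	physicochemical	[KR]{3,}
serine_content	amino-acid-content	S
proline_content	amino-acid-content	P
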