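# Representative medicinal-chemistry structural-alert rules.
# Columns: rule_id	category	smarts
# Binary reject: any match excludes the compound. A full external rule
# collection in the same format can be dropped in via config.
acyl_halide	acylating_agents	[CX3](=O)[Cl,Br,I]
sulfonyl_halide	acylating_agents	[SX4](=O)(=O)[Cl,Br]
acid_anhydride	acylating_agents	[CX3](=O)O[CX3](=O)
isocyanate	acylating_agents	[NX2]=C=O
isothiocyanate	acylating_agents	[NX2]=C=S
aldehyde_aliphatic	aldehydes	[CX3H1](=O)[CX4]
aldehyde_aromatic	aldehydes	[CX3H1](=O)c
catechol	chelators	c([OX2H])c([OX2H])
hydroxamic_acid	chelators	[CX3](=O)[NX3][OX2H]
michael_acceptor	reactive_electrophiles	[CX3]=[CX3][CX3]=[OX1]
epoxide	reactive_electrophiles	C1OC1
aziridine	reactive_electrophiles	C1NC1
alkyl_halide	reactive_electrophiles	[CX4][Cl,Br,I]
azide	reactive_electrophiles	[NX2]=[NX2+]=[NX1-]
thiol	thiols	[SX2H]
quinone	quinones	O=C1C=CC(=O)C=C1
nitro_aromatic	nitro_compounds	[$([NX3](=O)=O),$([NX3+](=O)[O-])]c
peroxide	peroxides	[OX2][OX2]
hydrazine	hydrazines	[NX3;H2][NX3;H1,H2]
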