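ALT	irr	alanine:1,glutamate:-1,oxoglutarate:1,pyruvate:-1
ALD	irr	alanine:-1,h:1,h2o:-1,nad:-1,nadh:1,nh4:1,pyruvate:1
BCAT_leu	irr	glutamate:-1,leucine:1,methyloxopentanoate:-1,oxoglutarate:1
BCD_leu	irr	h:1,h2o:-1,leucine:-1,methyloxopentanoate:1,nad:-1,nadh:1,nh4:1
BCAT_val	irr	glutamate:-1,methyloxobutanoate:-1,oxoglutarate:1,valine:1
BCD_val	irr	h:1,h2o:-1,methyloxobutanoate:1,nad:-1,nadh:1,nh4:1,valine:-1
ASPB	irr	aspartate:1,glutamate:-1,oxaloacetate:-1,oxoglutarate:1
ANSB	irr	aspartate:-1,fumarate:1,nh4:1
CITG	irr	fumarate:-1,h2o:-1,malate:1
MDH	irr	h:1,malate:-1,nad:-1,nadh:1,oxaloacetate:1
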