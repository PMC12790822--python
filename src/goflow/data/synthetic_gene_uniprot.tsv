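symbol	taxon	accession
PTEN	9606	P90001
SMAD4	9606	P90002
TP53	9606	P90003
VEGFA	9606	P90004
BCL2	9606	P90005
CDK6	9606	P90006
ZEB1	9606	P90007
SOX4	9606	P90008
PTEN	10090	Q90001
SMAD4	10090	Q90002
TP53	10090	Q90003
VEGFA	10090	Q90004
BCL2	10090	Q90005
CDK6	10090	Q90006
ZEB1	10090	Q90007
SOX4	10090	Q90008
PTEN	10116	R90001
SMAD4	10116	R90002
TP53	10116	R90003
VEGFA	10116	R90004
BCL2	10116	R90005
CDK6	10116	R90006
ZEB1	10116	R90007
SOX4	10116	R90008
PTEN	7955	S90001
SMAD4	7955	S90002
TP53	7955	S90003
VEGFA	7955	S90004
BCL2	7955	S90005
CDK6	7955	S90006
ZEB1	7955	S90007
SOX4	7955	S90008
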