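# Van der Waals radii (Å) used for solvent accessible surface area.
# Chothia-style radius set, keyed by element;
# atom-name overrides take precedence over element entries.
# kind is "element" or "name".
kind	key	radius
element	C	1.87
element	N	1.65
element	O	1.40
element	S	1.85
element	P	1.90
element	SE	1.90
element	F	1.47
element	CL	1.75
element	BR	1.85
element	I	1.98
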