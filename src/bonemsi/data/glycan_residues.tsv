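residue	formula
Hex	C6H10O5
HexNAc	C8H13NO5
HexA	C6H8O6
HexN	C6H11NO4
dHex	C6H10O4
NeuAc	C11H17NO8
NeuGc	C11H17NO9
Pen	C5H8O4
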