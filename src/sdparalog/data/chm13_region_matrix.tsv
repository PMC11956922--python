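label	NOTCH2	NOTCH2NLR	NOTCH2NLA	NOTCH2NLB	NOTCH2NLC
NOTCH2	x	115690	326052	556583	118987
NOTCH2NLR	99.7	x	342476	328624	217296
NOTCH2NLA	99.3	99.3	x	416088	182193
NOTCH2NLB	99.3	99.3	99.7	x	265598
NOTCH2NLC	99.2	99.0	99.1	99.2	x
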